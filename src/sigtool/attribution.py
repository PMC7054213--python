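"""Per-sample signature attribution with fixed profiles.

Given a signature set W, each sample's spectrum v is explained as v ~ W.a
with nonnegative activities a (the mutation counts attributed to each
signature).  The base fit minimises the Frobenius norm ||v - W.a|| over
a >= 0 — a convex problem whose optimum is solver-independent; we use the
deterministic active-set NNLS solver.  On top of that:

* an ``allowed`` subset (per-sample allow-list) forces the activities of
  biologically implausible signatures to exactly zero;
* :func:`sparse_attribute` performs backward elimination, dropping active
  signatures while the reconstruction cosine falls by at most a tolerance,
  to avoid spreading mutations over many tiny implausible contributions;
* :func:`attribute_ard` re-estimates the full activity matrix H by
  ARD-regularised multiplicative updates with W fixed, masked by a binary
  signature-by-sample indicator matrix Z (1 = allowed) applied after every
  update;
* :func:`mutation_probabilities` converts a sample's activities into
  per-class posterior probabilities that each signature caused a mutation
  of that class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalogue import MutationCatalogue
from .extraction import EPS, ExposureMatrix, SignatureSet

NNLS_TOL = 1e-10


@dataclass
class SampleAttribution:
    exposures: pd.Series  # indexed by signature name, mutation-count scale
    reconstruction_cosine: float
    residual_frobenius: float
    residual_kl: float
    log: list[str]


@dataclass
class AttributionResult:
    exposures: ExposureMatrix
    reconstruction_cosine: pd.Series  # per sample
    residual_frobenius: pd.Series
    residual_kl: pd.Series
    log: list[str]


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def _kl_vec(v: np.ndarray, r: np.ndarray) -> float:
    r = np.maximum(r, EPS)
    mask = v > 0
    return float(np.sum(v[mask] * np.log(v[mask] / r[mask])) - v.sum() + r.sum())


def attribute_sample(
    spectrum,
    signatures: SignatureSet,
    allowed: list[str] | None = None,
    renormalise: bool = False,
) -> SampleAttribution:
    """Nonnegative least-squares fit of one spectrum to fixed signatures.

    ``allowed`` restricts the fit to a signature subset (others are exactly
    zero).  With ``renormalise`` the activities are rescaled to sum to the
    observed mutation total.  An all-zero spectrum yields zero exposures
    with a warning rather than an error.
    """
    v = np.asarray(spectrum, dtype=float).ravel()
    if v.shape[0] != signatures.W.shape[0]:
        raise ValueError(
            f"spectrum length {v.shape[0]} != {signatures.W.shape[0]} classes"
        )
    if (v < 0).any():
        raise ValueError("spectrum must be nonnegative")
    names = signatures.names
    log: list[str] = []
    if allowed is None:
        allowed = names
    else:
        unknown = set(allowed) - set(names)
        if unknown:
            raise ValueError(f"unknown signatures in allow-list: {sorted(unknown)}")
    a = pd.Series(0.0, index=names)
    if v.sum() == 0:
        warnings.warn("all-zero spectrum: returning zero exposures", stacklevel=2)
        log.append("all-zero spectrum")
        return SampleAttribution(a, 0.0, 0.0, 0.0, log)
    cols = [n for n in names if n in set(allowed)]
    Wsub = signatures.profiles[cols].to_numpy()
    coef, _ = nnls(Wsub, v)
    coef[coef < NNLS_TOL] = 0.0
    a[cols] = coef
    if renormalise and a.sum() > 0:
        a *= v.sum() / a.sum()
        log.append("exposures renormalised to the observed mutation total")
    r = signatures.W @ a.to_numpy()
    return SampleAttribution(
        exposures=a,
        reconstruction_cosine=_cosine(v, r),
        residual_frobenius=float(np.linalg.norm(v - r)),
        residual_kl=_kl_vec(v, r),
        log=log,
    )


def sparse_attribute(
    spectrum,
    signatures: SignatureSet,
    allowed: list[str] | None = None,
    drop_tol: float = 0.01,
) -> SampleAttribution:
    """Backward-elimination sparsification of :func:`attribute_sample`.

    Starting from the full NNLS solution, repeatedly remove the active
    signature whose removal costs the least reconstruction cosine, as long
    as the cost is at most ``drop_tol``; refit after every removal.  With
    ``drop_tol = 0`` only numerically-zero activities are dropped.
    """
    base = attribute_sample(spectrum, signatures, allowed)
    v = np.asarray(spectrum, dtype=float).ravel()
    if v.sum() == 0:
        return base
    active = [n for n in base.exposures.index if base.exposures[n] > 0]
    best = base
    while len(active) > 1:
        candidates = []
        for n in active:
            trial = attribute_sample(v, signatures, [m for m in active if m != n])
            candidates.append((best.reconstruction_cosine - trial.reconstruction_cosine, n, trial))
        drop, name, trial = min(candidates, key=lambda t: (t[0], active.index(t[1])))
        if drop > drop_tol:
            break
        active.remove(name)
        best = trial
        best.log.append(f"dropped {name} (cosine cost {max(drop, 0.0):.2e})")
    return best


def attribute_catalogue(
    V: MutationCatalogue,
    signatures: SignatureSet,
    allowed: dict[str, list[str]] | None = None,
    sparse: float | None = None,
    renormalise: bool = False,
) -> AttributionResult:
    """Attribute every sample of a catalogue; thin loop over the per-sample fits."""
    rows = {}
    cos, fro, kl = {}, {}, {}
    log: list[str] = []
    for s in V.samples:
        v = V.counts[s].to_numpy(dtype=float)
        allow = None if allowed is None else allowed.get(s)
        if sparse is not None:
            res = sparse_attribute(v, signatures, allow, drop_tol=sparse)
        else:
            res = attribute_sample(v, signatures, allow, renormalise=renormalise)
        rows[s] = res.exposures
        cos[s], fro[s], kl[s] = (
            res.reconstruction_cosine,
            res.residual_frobenius,
            res.residual_kl,
        )
        log.extend(f"{s}: {msg}" for msg in res.log)
    H = pd.DataFrame(rows)[V.samples]
    return AttributionResult(
        exposures=ExposureMatrix(H),
        reconstruction_cosine=pd.Series(cos)[V.samples],
        residual_frobenius=pd.Series(fro)[V.samples],
        residual_kl=pd.Series(kl)[V.samples],
        log=log,
    )


def attribute_ard(
    V: MutationCatalogue,
    signatures: SignatureSet,
    Z: pd.DataFrame | np.ndarray | None = None,
    seed: int = 0,
    a: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    prune_fraction: float = 1e-2,
) -> ExposureMatrix:
    """ARD multiplicative updates on the activity matrix H with W fixed.

    ``Z`` is the binary signature-by-sample indicator matrix (1 = allowed);
    it is multiplied into H after every update, so disallowed entries are
    exactly zero throughout.  Per-signature relevance scales are estimated
    from the H rows only; rows whose relevance collapses are pruned to
    zero.  A sample whose Z column is all zero but whose spectrum is not
    triggers a warning and keeps zero exposures.
    """
    W = signatures.W
    Vm = V.values
    k, n = W.shape[1], Vm.shape[1]
    if Z is None:
        Zm = np.ones((k, n))
    elif isinstance(Z, pd.DataFrame):
        Zm = Z.reindex(index=signatures.names, columns=V.samples).to_numpy(dtype=float)
    else:
        Zm = np.asarray(Z, dtype=float)
    if Zm.shape != (k, n):
        raise ValueError(f"Z shape {Zm.shape} != {(k, n)}")
    if not np.isin(Zm, (0.0, 1.0)).all():
        raise ValueError("Z must be binary")
    dead = (Zm.sum(axis=0) == 0) & (Vm.sum(axis=0) > 0)
    if dead.any():
        bad = [V.samples[j] for j in np.flatnonzero(dead)]
        warnings.warn(
            f"samples with all-zero indicator column get zero exposures: {bad}",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    H = rng.uniform(0.5, 1.5, size=(k, n)) * max(Vm.mean(), EPS) * Zm
    b = max(np.sqrt(max((a - 1) * (a - 2), EPS) * Vm.mean() / k), EPS)
    denom = n + a + 1
    wsum = W.sum(axis=0)[:, None]

    def kl_obj(H):
        R = np.maximum(W @ H, EPS)
        mask = Vm > 0
        return float(np.sum(Vm[mask] * np.log(Vm[mask] / R[mask])) - Vm.sum() + R.sum())

    prev = np.inf
    for it in range(1, max_iter + 1):
        lam = (H.sum(axis=1) + b) / denom
        R = np.maximum(W @ H, EPS)
        H = H * (W.T @ (Vm / R)) / (wsum + 1.0 / lam[:, None])
        H *= Zm
        if it % 10 == 0 or it == max_iter:
            obj = kl_obj(H) + float(np.sum((H.sum(axis=1) + b) / lam) + denom * np.log(lam).sum())
            if abs(prev - obj) <= tol * max(abs(prev), 1.0):
                break
            prev = obj
    mass = H.sum(axis=1)
    H[mass < prune_fraction * max(mass.max(), EPS), :] = 0.0
    return ExposureMatrix(pd.DataFrame(H, index=signatures.names, columns=V.samples))


def mutation_probabilities(signatures: SignatureSet, exposures) -> pd.DataFrame:
    """Per-class probability that each signature generated a mutation.

    ``P[i, k] = W[i, k] h[k] / sum_k' W[i, k'] h[k']``; rows with zero
    reconstructed mass are returned as NaN (undefined).
    """
    h = np.asarray(exposures, dtype=float).ravel()
    if h.shape[0] != len(signatures):
        raise ValueError("exposure vector length != number of signatures")
    if (h < 0).any():
        raise ValueError("exposures must be nonnegative")
    if h.sum() == 0:
        raise ValueError("all-zero exposure vector: probabilities undefined")
    num = signatures.W * h[None, :]
    den = num.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(den > 0, num / np.maximum(den, EPS), np.nan)
    return pd.DataFrame(P, index=signatures.profiles.index, columns=signatures.names)
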