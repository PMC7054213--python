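"""De novo mutational-signature extraction.

Two NMF families are implemented on the catalogue matrix V (classes x
samples, V ~ W.H with W the signature profiles and H the per-sample
activities):

* **Bootstrap consensus KL-NMF** (:func:`extract_signatures`) — many NMF
  runs, each on a multinomial bootstrap of every sample's spectrum,
  minimising the generalized Kullback-Leibler divergence by multiplicative
  updates; the pooled per-run signatures are clustered (one signature per
  run per cluster, matched by the Hungarian algorithm under cosine
  distance) and cluster stability (mean silhouette) together with
  reconstruction error drives rank selection.  Selection is advisory:
  the full per-rank table is returned for human assessment.
* **ARD Bayesian NMF** (:func:`ard_nmf`) — KL likelihood with per-component
  exponential (or half-normal) priors whose relevance scales are updated in
  closed form; irrelevant components shrink to zero and are pruned, so the
  number of signatures is inferred rather than fixed.  The best of several
  random restarts by log posterior is returned.
* **Two-step extraction** (:func:`two_step_extract`) — signatures are first
  extracted from samples with ordinary mutation burdens; hypermutated
  samples are then explained by those fixed profiles plus additional free
  components, so hypermutators can contribute new signatures without
  distorting the profiles learned from the bulk of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_score

from .catalogue import ClassificationSchema, MutationCatalogue

EPS = 1e-16


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """W matrix: classes x signatures, each column a probability profile."""

    schema: ClassificationSchema
    profiles: pd.DataFrame  # index = class labels, columns = signature names

    def __post_init__(self):
        W = self.profiles.to_numpy(dtype=float)
        if (W < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        colsum = W.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError("signature profile with zero mass")
        self.profiles = self.profiles / colsum

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def W(self) -> np.ndarray:
        return self.profiles.to_numpy(dtype=float)

    def __len__(self) -> int:
        return self.profiles.shape[1]

    def subset(self, names: list[str]) -> "SignatureSet":
        return SignatureSet(self.schema, self.profiles[names].copy())

    def to_csv(self, path: str) -> None:
        self.profiles.rename_axis("MutationType").to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str, schema_name: str) -> "SignatureSet":
        df = pd.read_csv(path, index_col=0)
        df.index.name = None
        return cls(ClassificationSchema(schema_name), df)


@dataclass
class ExposureMatrix:
    """H matrix: signatures x samples, attributed mutation counts."""

    activities: pd.DataFrame  # index = signature names, columns = samples

    def __post_init__(self):
        if (self.activities.to_numpy(dtype=float) < 0).any():
            raise ValueError("exposures must be nonnegative")

    @property
    def H(self) -> np.ndarray:
        return self.activities.to_numpy(dtype=float)

    @property
    def samples(self) -> list[str]:
        return list(self.activities.columns)

    def to_csv(self, path: str) -> None:
        self.activities.rename_axis("Signature").to_csv(path, float_format="%.10g")


@dataclass
class RankResult:
    k: int
    signatures: SignatureSet
    exposures: ExposureMatrix
    stability: float
    kl_error: float
    frobenius_error: float
    n_iterations: int
    seed: int


@dataclass
class ExtractionSolution:
    per_rank: dict[int, RankResult]
    selected_rank: int
    selection_note: str = field(default="advisory; review the stability/error table")

    @property
    def selected(self) -> RankResult:
        return self.per_rank[self.selected_rank]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "k": r.k,
                "stability": r.stability,
                "kl_error": r.kl_error,
                "frobenius_error": r.frobenius_error,
            }
            for r in self.per_rank.values()
        ]
        return pd.DataFrame(rows).set_index("k")


# ---------------------------------------------------------------------------
# generalized KL NMF with multiplicative updates
# ---------------------------------------------------------------------------

def generalized_kl(V: np.ndarray, R: np.ndarray) -> float:
    """D(V || R) = sum V log(V/R) - V + R, with 0 log 0 = 0."""
    V = np.asarray(V, dtype=float)
    R = np.maximum(np.asarray(R, dtype=float), EPS)
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / R[mask])) - V.sum() + R.sum())


def _as_matrix(V) -> np.ndarray:
    if isinstance(V, MutationCatalogue):
        return V.values
    return np.asarray(V, dtype=float)


def nmf_kl(
    V,
    k: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    check_every: int = 10,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Rank-k NMF minimising the generalized KL divergence.

    Standard multiplicative updates (monotonically non-increasing
    objective); stops when the relative objective change over
    ``check_every`` iterations drops below ``tol``.  W columns are
    renormalised to sum 1 with the scale folded into H.  Returns
    ``(W, H, objective_trace)``.
    """
    V = _as_matrix(V)
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    n_classes, n_samples = V.shape
    if (V.sum(axis=0) == 0).any():
        raise ValueError("V has an all-zero sample column; remove it before factorisation")
    if not 1 <= k <= min(n_classes, n_samples):
        raise ValueError(f"rank k={k} outside [1, {min(n_classes, n_samples)}]")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.5, 1.5, size=(n_classes, k)) * scale
    H = rng.uniform(0.5, 1.5, size=(k, n_samples)) * scale

    trace = [generalized_kl(V, W @ H)]
    for it in range(1, max_iter + 1):
        R = np.maximum(W @ H, EPS)
        W *= (V / R) @ H.T / np.maximum(H.sum(axis=1), EPS)
        R = np.maximum(W @ H, EPS)
        H *= W.T @ (V / R) / np.maximum(W.sum(axis=0), EPS)[:, None]
        if it % check_every == 0 or it == max_iter:
            obj = generalized_kl(V, W @ H)
            prev = trace[-1]
            trace.append(obj)
            if prev - obj <= tol * max(abs(prev), 1.0):
                break

    col = np.maximum(W.sum(axis=0), EPS)
    W = W / col
    H = H * col[:, None]
    return W, H, trace


def bootstrap_catalogue(V: MutationCatalogue, seed: int) -> MutationCatalogue:
    """Multinomial resample of each sample's spectrum, preserving totals."""
    rng = np.random.default_rng(seed)
    counts = V.counts.to_numpy()
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        total = int(counts[:, j].sum())
        if total == 0:
            continue
        p = counts[:, j] / total
        out[:, j] = rng.multinomial(total, p)
    df = pd.DataFrame(out, index=V.counts.index, columns=V.counts.columns)
    return MutationCatalogue(V.schema, df)


# ---------------------------------------------------------------------------
# consensus clustering of bootstrap signatures
# ---------------------------------------------------------------------------

def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=0), EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), EPS)
    return An.T @ Bn


def _consensus_cluster(
    stacks: list[np.ndarray], seed: int, max_rounds: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Partition pooled per-iteration signatures into k clusters.

    Each NMF iteration contributes exactly one signature per cluster
    (Hungarian matching of its k columns to the k current centroids under
    cosine similarity), which prevents cluster collapse.  Returns
    ``(centroids, labels)`` with labels aligned to the pooled column order.
    """
    k = stacks[0].shape[1]
    rng = np.random.default_rng(seed)
    centroids = stacks[rng.integers(len(stacks))].copy()
    labels = np.zeros(len(stacks) * k, dtype=int)
    for _ in range(max_rounds):
        prev = labels.copy()
        sums = np.zeros_like(centroids)
        for i, S in enumerate(stacks):
            sim = _cosine_matrix(S, centroids)
            rows, cols = linear_sum_assignment(-sim)
            labels[i * k + rows] = cols
            for r, c in zip(rows, cols):
                sums[:, c] += S[:, r] / max(np.linalg.norm(S[:, r]), EPS)
        centroids = sums / np.maximum(np.linalg.norm(sums, axis=0), EPS)
        if np.array_equal(prev, labels):
            break
    return centroids, labels


def _iteration_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=key)


def extract_signatures(
    V: MutationCatalogue,
    k_range,
    n_iterations: int = 1024,
    seed: int = 0,
    stability_min: float = 0.8,
    gain_min: float = 0.02,
    nmf_tol: float = 1e-6,
    nmf_max_iter: int = 1000,
    signature_prefix: str = "S",
) -> ExtractionSolution:
    """Bootstrap-consensus KL-NMF over a range of candidate ranks.

    For each rank k, ``n_iterations`` NMF runs on bootstrap-resampled
    catalogues are pooled and consensus-clustered; the consensus W is the
    normalised cluster centroid and the consensus H attributes the original
    (un-resampled) catalogue by nonnegative least squares.  The selected
    rank is the largest k whose stability is at least ``stability_min``
    and whose relative KL improvement over the previous rank is at least
    ``gain_min`` (the smallest rank needs only the stability condition);
    the choice is advisory and the full table is returned.
    """
    from .attribution import attribute_catalogue

    k_range = sorted(set(int(k) for k in k_range))
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2 for consensus stability")
    per_rank: dict[int, RankResult] = {}
    Vmat = V.values

    for k in k_range:
        stacks: list[np.ndarray] = []
        for it in range(n_iterations):
            ss = _iteration_seed(seed, k, it)
            boot_seed, nmf_seed = ss.generate_state(2)
            Vb = bootstrap_catalogue(V, int(boot_seed))
            W, _, _ = nmf_kl(Vb, k, seed=int(nmf_seed), tol=nmf_tol, max_iter=nmf_max_iter)
            stacks.append(W)
        centroids, labels = _consensus_cluster(
            stacks, seed=int(_iteration_seed(seed, k, n_iterations).generate_state(1)[0])
        )
        pooled = np.concatenate(stacks, axis=1)
        if k == 1:
            stability = 1.0
        else:
            stability = float(
                silhouette_score(pooled.T, labels, metric="cosine")
            )
        Wc = centroids / np.maximum(centroids.sum(axis=0), EPS)
        names = [f"{signature_prefix}{k}-{i + 1}" for i in range(k)]
        sigs = SignatureSet(
            V.schema, pd.DataFrame(Wc, index=V.counts.index, columns=names)
        )
        exposures = attribute_catalogue(V, sigs).exposures
        R = Wc @ exposures.H
        per_rank[k] = RankResult(
            k=k,
            signatures=sigs,
            exposures=exposures,
            stability=stability,
            kl_error=generalized_kl(Vmat, R),
            frobenius_error=float(np.linalg.norm(Vmat - R)),
            n_iterations=n_iterations,
            seed=seed,
        )

    selected = k_range[0]
    for prev_k, k in zip(k_range, k_range[1:]):
        r, rp = per_rank[k], per_rank[prev_k]
        gain = (rp.kl_error - r.kl_error) / max(rp.kl_error, EPS)
        if r.stability >= stability_min and gain >= gain_min:
            selected = k
    if per_rank[selected].stability < stability_min and len(k_range) > 1:
        # no rank is stable enough; fall back to the most stable one
        selected = max(per_rank, key=lambda k: per_rank[k].stability)
    return ExtractionSolution(per_rank=per_rank, selected_rank=selected)


def reconstruction_cosines(V: MutationCatalogue, signatures: SignatureSet, exposures: ExposureMatrix) -> pd.Series:
    """Per-sample cosine similarity between observed and reconstructed spectra."""
    Vm = V.values
    R = signatures.W @ exposures.H
    num = (Vm * R).sum(axis=0)
    den = np.linalg.norm(Vm, axis=0) * np.linalg.norm(R, axis=0)
    return pd.Series(num / np.maximum(den, EPS), index=V.samples)


@dataclass
class HierarchicalReport:
    levels: list[dict]
    signatures: SignatureSet


def hierarchical_extract(
    V: MutationCatalogue,
    k_range,
    recon_threshold: float = 0.95,
    max_levels: int = 3,
    novelty_max: float = 0.9,
    seed: int = 0,
    **extract_kwargs,
) -> HierarchicalReport:
    """Hierarchical re-extraction to rescue rare or low-burden signatures.

    Level 1 extracts from the full cohort; samples whose reconstruction
    cosine falls below ``recon_threshold`` form the next level's input.
    Signatures from deeper levels are appended only when novel (cosine
    below ``novelty_max`` to every signature already collected).
    """
    current = V
    collected: pd.DataFrame | None = None
    levels: list[dict] = []
    for level in range(1, max_levels + 1):
        nonzero = [s for s in current.samples if current.counts[s].sum() > 0]
        current = MutationCatalogue(current.schema, current.counts[nonzero])
        level_ks = [k for k in k_range if k <= min(current.counts.shape)]
        sol = extract_signatures(
            current, level_ks, seed=seed + level - 1, **extract_kwargs
        )
        best = sol.selected
        novel = []
        for name in best.signatures.names:
            profile = best.signatures.profiles[name]
            if collected is None:
                is_novel = True
            else:
                sims = _cosine_matrix(
                    profile.to_numpy()[:, None], collected.to_numpy()
                )[0]
                is_novel = bool((sims < novelty_max).all())
            if is_novel:
                novel.append(name)
                col = profile.rename(f"L{level}:{name}")
                collected = col.to_frame() if collected is None else collected.join(col)
        cosines = reconstruction_cosines(current, best.signatures, best.exposures)
        failing = [s for s in current.samples if cosines[s] < recon_threshold]
        levels.append(
            {
                "level": level,
                "n_samples": len(current.samples),
                "selected_rank": sol.selected_rank,
                "novel_signatures": novel,
                "n_failing": len(failing),
            }
        )
        if not failing or level == max_levels:
            if not failing and level == 1:
                levels[-1]["note"] = "all samples reconstructed at level 1"
            break
        current = MutationCatalogue(V.schema, current.counts[failing])
    sigs = SignatureSet(V.schema, collected)
    return HierarchicalReport(levels=levels, signatures=sigs)


# ---------------------------------------------------------------------------
# ARD Bayesian NMF
# ---------------------------------------------------------------------------

@dataclass
class ArdResult:
    W: np.ndarray
    H: np.ndarray
    relevance: np.ndarray  # per retained component
    log_posterior: float
    effective_rank: int
    trace: list[float]


def _ard_once(
    V: np.ndarray,
    k_max: int,
    prior: str,
    seed: int,
    a: float,
    tol: float,
    max_iter: int,
    W_fixed: np.ndarray | None = None,
    H_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    n_classes, n_samples = V.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k_max)
    n_fixed = 0 if W_fixed is None else W_fixed.shape[1]
    k_total = n_fixed + k_max
    W = rng.uniform(0.5, 1.5, size=(n_classes, k_total)) * scale
    H = rng.uniform(0.5, 1.5, size=(k_total, n_samples)) * scale
    if W_fixed is not None:
        # free components start small so the established profiles explain
        # the bulk of the data and free ones grow only where it demands
        W[:, n_fixed:] *= 1e-3
        H[n_fixed:, :] *= 1e-3
        W[:, :n_fixed] = W_fixed
    if H_mask is not None:
        H *= H_mask

    if prior == "exponential":
        b = np.sqrt((a - 1) * (a - 2) * V.mean() / k_total)
        denom_lam = n_classes + n_samples + a + 1
    elif prior == "half-normal":
        b = (a - 1) * V.mean() / k_total
        denom_lam = (n_classes + n_samples) / 2 + a + 1
    else:
        raise ValueError("prior must be 'exponential' or 'half-normal'")
    b = max(b, EPS)

    def lam_of(W, H):
        if prior == "exponential":
            return (W.sum(axis=0) + H.sum(axis=1) + b) / denom_lam
        return (0.5 * ((W**2).sum(axis=0) + (H**2).sum(axis=1)) + b) / denom_lam

    lam = lam_of(W, H)

    def objective(W, H, lam):
        d = generalized_kl(V, W @ H)
        if prior == "exponential":
            pen = np.sum((W.sum(axis=0) + H.sum(axis=1) + b) / lam) + denom_lam * np.sum(
                np.log(lam)
            )
        else:
            pen = np.sum(
                (0.5 * ((W**2).sum(axis=0) + (H**2).sum(axis=1)) + b) / lam
            ) + denom_lam * np.sum(np.log(lam))
        return d + pen

    trace = [objective(W, H, lam)]
    for it in range(1, max_iter + 1):
        R = np.maximum(W @ H, EPS)
        if prior == "exponential":
            W_new = W * ((V / R) @ H.T) / (H.sum(axis=1)[None, :] + 1.0 / lam[None, :])
        else:
            W_new = W * ((V / R) @ H.T) / (H.sum(axis=1)[None, :] + W / lam[None, :])
        if W_fixed is not None:
            W_new[:, :n_fixed] = W_fixed
        W = W_new
        R = np.maximum(W @ H, EPS)
        if prior == "exponential":
            H = H * (W.T @ (V / R)) / (W.sum(axis=0)[:, None] + 1.0 / lam[:, None])
        else:
            H = H * (W.T @ (V / R)) / (W.sum(axis=0)[:, None] + H / lam[:, None])
        if H_mask is not None:
            H *= H_mask
        lam = lam_of(W, H)
        if it % 10 == 0 or it == max_iter:
            obj = objective(W, H, lam)
            prev = trace[-1]
            trace.append(obj)
            if abs(prev - obj) <= tol * max(abs(prev), 1.0):
                break
    return W, H, lam, -trace[-1], trace


def ard_nmf(
    V,
    k_max: int,
    prior: str = "exponential",
    seed: int = 0,
    n_restarts: int = 10,
    a: float = 10.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    prune_fraction: float = 1e-2,
) -> ArdResult:
    """Bayesian NMF with automatic relevance determination.

    Each component carries a relevance scale (exponential or half-normal
    prior on its W column and H row, inverse-gamma hyperprior with shape
    ``a``); closed-form relevance updates drive unneeded components toward
    zero.  Components whose relevance falls below ``prune_fraction`` times
    the maximum are removed after convergence.  The best of ``n_restarts``
    runs by log posterior is returned; the effective rank is the number of
    surviving components.
    """
    V = _as_matrix(V)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    best: tuple | None = None
    for r in range(n_restarts):
        run_seed = int(_iteration_seed(seed, r).generate_state(1)[0])
        W, H, lam, logpost, trace = _ard_once(
            V, k_max, prior, run_seed, a, tol, max_iter
        )
        if best is None or logpost > best[3]:
            best = (W, H, lam, logpost, trace)
    W, H, lam, logpost, trace = best
    keep = _relevance_keep(W, H, lam, prune_fraction)
    W, H, lam = W[:, keep], H[keep], lam[keep]
    col = np.maximum(W.sum(axis=0), EPS)
    return ArdResult(
        W=W / col,
        H=H * col[:, None],
        relevance=lam,
        log_posterior=logpost,
        effective_rank=int(keep.sum()),
        trace=trace,
    )


def _relevance_keep(W: np.ndarray, H: np.ndarray, lam: np.ndarray, frac: float) -> np.ndarray:
    # component mass is the natural relevance readout: pruned components'
    # W columns and H rows have shrunk to ~0 regardless of lambda's floor
    mass = W.sum(axis=0) * H.sum(axis=1)
    return mass > frac * max(mass.max(), EPS)


@dataclass
class TwoStepResult:
    signatures: SignatureSet          # step-1 profiles followed by hyper-only ones
    hyper_only: list[str]
    exposures_low: ExposureMatrix
    exposures_hyper: ExposureMatrix
    step1: ArdResult


def _refit_h(V: np.ndarray, W: np.ndarray, H: np.ndarray, n_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    """Plain multiplicative KL updates of H with W fixed (no prior)."""
    wsum = np.maximum(W.sum(axis=0), EPS)[:, None]
    prev = np.inf
    for it in range(n_iter):
        R = np.maximum(W @ H, EPS)
        H = H * (W.T @ (V / R)) / wsum
        if it % 20 == 19:
            obj = generalized_kl(V, W @ H)
            if prev - obj <= tol * max(abs(prev), 1.0):
                break
            prev = obj
    return H


def two_step_extract(
    V_low: MutationCatalogue,
    V_hyper: MutationCatalogue | None,
    k_max: int,
    seed: int = 0,
    prior: str = "exponential",
    n_restarts: int = 10,
    novelty_max: float = 0.9,
    **ard_kwargs,
) -> TwoStepResult:
    """ARD extraction with the hypermutated samples handled separately.

    Step 1 runs :func:`ard_nmf` on the low-burden catalogue.  Step 2 runs
    ARD updates on the hypermutated catalogue with the step-1 profiles held
    exactly fixed plus ``k_max`` additional free components; free
    components that survive relevance pruning and are novel (cosine below
    ``novelty_max`` to every fixed profile and to every stronger free
    component — near-duplicates arise when a free component merely corrects
    a fixed profile's estimation error, or when one novel process splits
    across two components) are the hyper-only signatures; the hypermutator
    exposures are then refit on the deduplicated signature set.  This
    prevents hypermutators from distorting the cohort-wide profiles, and
    hyper-only signatures must never be offered when attributing low-burden
    samples.
    """
    if set(V_low.samples) & set(V_hyper.samples if V_hyper is not None else []):
        raise ValueError("low-burden and hypermutated sample sets must be disjoint")
    step1 = ard_nmf(
        V_low, k_max, prior=prior, seed=seed, n_restarts=n_restarts, **ard_kwargs
    )
    names1 = [f"S{i + 1}" for i in range(step1.effective_rank)]
    profiles = pd.DataFrame(step1.W, index=V_low.counts.index, columns=names1)
    exposures_low = ExposureMatrix(
        pd.DataFrame(step1.H, index=names1, columns=V_low.samples)
    )
    if V_hyper is None or len(V_hyper.samples) == 0:
        sigs = SignatureSet(V_low.schema, profiles)
        empty = ExposureMatrix(pd.DataFrame(np.zeros((len(names1), 0)), index=names1, columns=[]))
        return TwoStepResult(sigs, [], exposures_low, empty, step1)

    Vh = V_hyper.values
    a = ard_kwargs.get("a", 10.0)
    tol = ard_kwargs.get("tol", 1e-8)
    max_iter = ard_kwargs.get("max_iter", 10_000)
    prune_fraction = ard_kwargs.get("prune_fraction", 1e-2)
    best = None
    for r in range(n_restarts):
        run_seed = int(_iteration_seed(seed, 1_000_000 + r).generate_state(1)[0])
        W, H, lam, logpost, _ = _ard_once(
            Vh, k_max, prior, run_seed, a, tol, max_iter, W_fixed=step1.W
        )
        if best is None or logpost > best[3]:
            best = (W, H, lam, logpost)
    W, H, lam, _ = best
    n_fixed = step1.effective_rank
    keep = _relevance_keep(W, H, lam, prune_fraction)
    # novelty dedup: strongest surviving free components first
    mass = W.sum(axis=0) * H.sum(axis=1)
    survivors = sorted(
        (i for i in range(n_fixed, W.shape[1]) if keep[i]),
        key=lambda i: -mass[i],
    )
    kept_free: list[int] = []
    for i in survivors:
        others = np.column_stack([step1.W] + [W[:, j] for j in kept_free]) if (n_fixed or kept_free) else None
        if others is not None:
            sims = _cosine_matrix(W[:, i : i + 1], others)[0]
            if (sims >= novelty_max).any():
                continue
        kept_free.append(i)
    cols = list(range(n_fixed)) + kept_free
    W, H = W[:, cols], H[cols]
    W[:, :n_fixed] = step1.W  # exact fixed-profile contract
    H = _refit_h(Vh, W, H)
    hyper_names = [f"H{i + 1}" for i in range(len(kept_free))]
    names = names1 + hyper_names
    col = np.maximum(W.sum(axis=0), EPS)
    Wn, Hn = W / col, H * col[:, None]
    Wn[:, :n_fixed] = step1.W
    sigs = SignatureSet(
        V_low.schema, pd.DataFrame(Wn, index=V_low.counts.index, columns=names)
    )
    # bypass renormalisation rounding: fixed columns are bitwise step-1 W
    sigs.profiles.iloc[:, :n_fixed] = step1.W
    exposures_hyper = ExposureMatrix(
        pd.DataFrame(Hn, index=names, columns=V_hyper.samples)
    )
    return TwoStepResult(sigs, hyper_names, exposures_low, exposures_hyper, step1)


def burden_quantile_split(
    V: MutationCatalogue, quantile: float = 0.95
) -> tuple[list[str], list[str]]:
    """Heuristic hypermutator split by total-burden quantile.

    Convenience only: the biologically meaningful split (mismatch-repair
    deficiency, POLE, UV, treatment exposure) is cohort knowledge the
    caller should supply as explicit sample lists.
    """
    totals = V.counts.sum(axis=0)
    cut = totals.quantile(quantile)
    hyper = [s for s in V.samples if totals[s] > cut]
    low = [s for s in V.samples if totals[s] <= cut]
    return low, hyper
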