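"""Ground-truthed synthetic inputs for validation.

Two generators:

* :func:`simulate_catalogue` draws mutation catalogues from known signature
  profiles and per-sample exposures — burdens log-uniform over orders of
  magnitude, optional hypermutated subpopulation, Poisson or multinomial
  counting noise — and returns the ground-truth exposure matrix alongside,
  so extraction and attribution can be scored against a known answer.
* :func:`simulate_genome_and_vcf` writes a random toy genome (FASTA) plus a
  standards-conformant VCF of implanted SBS/DBS/indel events whose true
  classes are computed *at generation time* from the construction itself
  (with this module's own, deliberately independent labelling arithmetic),
  so catalogue construction can be round-trip tested without any reference
  download.

Shipped-in-code fixture signatures (:func:`synthetic_signatures`) are
synthetic but structured — sparse, peaked profiles with controlled pairwise
cosines — standing in for real reference profiles so tests need no network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalogue import ClassificationSchema, MutationCatalogue
from .extraction import ExposureMatrix, SignatureSet
from .io import write_fasta, write_vcf
from .catalogue import GenomicMutation, MutationKind

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# fixture signature profiles
# ---------------------------------------------------------------------------

def synthetic_signatures(
    schema_name: str,
    n_signatures: int,
    seed: int = 0,
    n_peaks: int = 8,
    background: float = 0.02,
    max_pairwise_cosine: float = 0.3,
    max_tries: int = 200,
    name_prefix: str = "SYN",
) -> SignatureSet:
    """Sparse, peaked synthetic signature profiles with bounded similarity.

    Each profile concentrates its mass on ``n_peaks`` randomly chosen
    classes (Dirichlet weights) over a small uniform background.  Columns
    are resampled until all pairwise cosines are below
    ``max_pairwise_cosine`` (rejection, seeded).
    """
    schema = ClassificationSchema(schema_name)
    n_classes = len(schema)
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    tries = 0
    while len(cols) < n_signatures:
        if tries > max_tries:
            raise RuntimeError(
                "could not draw signatures under the pairwise-cosine bound; "
                "raise max_pairwise_cosine or lower n_signatures"
            )
        tries += 1
        peaks = rng.choice(n_classes, size=min(n_peaks, n_classes), replace=False)
        w = np.full(n_classes, background / n_classes)
        w[peaks] += (1 - background) * rng.dirichlet(np.ones(len(peaks)))
        w /= w.sum()
        ok = all(
            float(w @ c / (np.linalg.norm(w) * np.linalg.norm(c))) < max_pairwise_cosine
            for c in cols
        )
        if ok:
            cols.append(w)
    W = np.column_stack(cols)
    names = [f"{name_prefix}{i + 1}" for i in range(n_signatures)]
    return SignatureSet(
        schema, pd.DataFrame(W, index=list(schema.classes), columns=names)
    )


# ---------------------------------------------------------------------------
# catalogue simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationScenario:
    """One synthetic-cohort configuration (the study conditions, not a dial).

    Burdens are drawn log-uniformly over ``burden_range`` (default
    10^2-10^4 mutations, emulating the orders-of-magnitude spread of real
    cohorts); a ``hyper_fraction`` of samples is additionally multiplied by
    ``hyper_multiplier`` (default 100x).  Signature mixtures are Dirichlet
    with concentration ``dirichlet_alpha`` per signature.
    """

    name: str
    signatures: SignatureSet
    n_samples: int
    seed: int
    burden_range: tuple[float, float] = (1e2, 1e4)
    dirichlet_alpha: float = 1.0
    hyper_fraction: float = 0.0
    hyper_multiplier: float = 100.0
    noise: str = "poisson"  # poisson | multinomial | none

    def __post_init__(self):
        lo, hi = self.burden_range
        if lo <= 0 or hi < lo:
            raise ValueError("burden_range must be positive and ordered")
        if not 0 <= self.hyper_fraction < 1:
            raise ValueError("hyper_fraction must lie in [0, 1)")
        if self.noise not in ("poisson", "multinomial", "none"):
            raise ValueError("noise must be poisson, multinomial or none")


@dataclass
class SimulatedCohort:
    catalogue: MutationCatalogue
    exposures: ExposureMatrix  # ground truth
    hyper_samples: list[str]
    scenario: SimulationScenario


def simulate_catalogue(scenario: SimulationScenario) -> SimulatedCohort:
    """Draw a catalogue and its ground-truth exposures from a scenario.

    Multinomial noise conserves each sample's intended burden exactly (the
    truth exposures are the per-signature multinomial counts); Poisson
    noise conserves it in expectation (the truth exposures are the
    per-signature means).  ``noise="none"`` rounds the expected spectrum.
    """
    sigs = scenario.signatures
    W = sigs.W
    k = W.shape[1]
    rng = np.random.default_rng(scenario.seed)
    lo, hi = scenario.burden_range
    samples = [f"{scenario.name}::s{i + 1}" for i in range(scenario.n_samples)]
    n_hyper = int(round(scenario.hyper_fraction * scenario.n_samples))
    hyper_idx = set(
        rng.choice(scenario.n_samples, size=n_hyper, replace=False).tolist()
    )
    counts = np.zeros((W.shape[0], scenario.n_samples))
    truth = np.zeros((k, scenario.n_samples))
    for j in range(scenario.n_samples):
        burden = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if j in hyper_idx:
            burden *= scenario.hyper_multiplier
        mix = rng.dirichlet(np.full(k, scenario.dirichlet_alpha))
        if scenario.noise == "multinomial":
            per_sig = rng.multinomial(int(round(burden)), mix)
            truth[:, j] = per_sig
            for s in range(k):
                if per_sig[s]:
                    counts[:, j] += rng.multinomial(per_sig[s], W[:, s])
        else:
            truth[:, j] = burden * mix
            expected = W @ truth[:, j]
            if scenario.noise == "poisson":
                counts[:, j] = rng.poisson(expected)
            else:
                counts[:, j] = np.round(expected)
    catalogue = MutationCatalogue(
        sigs.schema,
        pd.DataFrame(
            counts.astype(int), index=sigs.profiles.index, columns=samples
        ),
    )
    exposures = ExposureMatrix(pd.DataFrame(truth, index=sigs.names, columns=samples))
    return SimulatedCohort(
        catalogue=catalogue,
        exposures=exposures,
        hyper_samples=[samples[i] for i in sorted(hyper_idx)],
        scenario=scenario,
    )


def scenario_suite(scale: str = "desk", seed: int = 0) -> list[SimulationScenario]:
    """Paired cross-design scenarios from two fixture reference sets.

    Profiles from set A with A-style exposures, B with B-style, and the
    two cross combinations (A-profiles/B-exposures and vice versa) — four
    data types per test.  Desk scale uses cohorts of at most 300 samples;
    full scale multiplies the sample counts by 20.
    """
    if scale not in ("desk", "full"):
        raise ValueError("scale must be 'desk' or 'full'")
    mult = 1 if scale == "desk" else 20
    sigs_a = synthetic_signatures("SBS96", 4, seed=seed, name_prefix="A")
    sigs_b = synthetic_signatures("SBS96", 5, seed=seed + 1, name_prefix="B")
    # A-style exposures: moderate burdens, even mixtures; B-style: heavier
    # spread with a hypermutated subpopulation and sparser mixtures.
    style_a = dict(burden_range=(3e2, 3e3), dirichlet_alpha=1.0, hyper_fraction=0.0)
    style_b = dict(
        burden_range=(1e2, 1e4),
        dirichlet_alpha=0.5,
        hyper_fraction=0.05,
        hyper_multiplier=100.0,
    )
    combos = [
        ("A-profiles_A-exposures", sigs_a, style_a),
        ("B-profiles_B-exposures", sigs_b, style_b),
        ("A-profiles_B-exposures", sigs_a, style_b),
        ("B-profiles_A-exposures", sigs_b, style_a),
    ]
    return [
        SimulationScenario(
            name=name,
            signatures=sigs,
            n_samples=150 * mult,
            seed=seed + 10 + i,
            noise="poisson",
            **style,
        )
        for i, (name, sigs, style) in enumerate(combos)
    ]


# ---------------------------------------------------------------------------
# toy genome + VCF with generation-time truth
# ---------------------------------------------------------------------------

# The truth labels below are computed with this module's own arithmetic
# (pyrimidine collapse, doublet canonicalisation, indel bins) written
# directly from the construction parameters, independent of the catalogue
# classifiers they are used to test.

def _sbs_truth(ctx3: str, alt: str) -> str:
    ref = ctx3[1]
    if ref in "AG":
        ctx3, ref, alt = _rc(ctx3), _COMP[ref], _COMP[alt]
    return f"{ctx3[0]}[{ref}>{alt}]{ctx3[2]}"


def _dbs_truth(ref2: str, alt2: str) -> str:
    pair = (ref2, alt2)
    rc_pair = (_rc(ref2), _rc(alt2))
    ref2, alt2 = min(pair, rc_pair)
    return f"{ref2}>{alt2}"


@dataclass
class SimulatedVariantData:
    fasta_path: str
    vcf_path: str
    sample_id: str
    mutations: list[GenomicMutation]
    truth: dict[str, pd.DataFrame]  # schema -> classes x [sample] counts
    genome: dict[str, str] = field(repr=False, default_factory=dict)


def simulate_genome_and_vcf(
    genome_length: int,
    n_sbs: int,
    n_dbs: int,
    n_indels: int,
    seed: int,
    out_dir: str,
    sample_id: str = "SYN-1",
    chrom: str = "chrSyn",
) -> SimulatedVariantData:
    """Random toy genome plus a VCF of implanted events with known classes.

    Events are placed in non-overlapping slots; around each indel the
    local sequence is overwritten with a controlled motif (homopolymer
    run, tandem repeat or microhomology junction flanked by guard bases)
    so the event's true ID83 class is fixed by construction.  Raises when
    the requested events cannot be hosted without overlap.
    """
    import os

    rng = np.random.default_rng(seed)
    n_events = n_sbs + n_dbs + n_indels
    slot = 80  # room for a 5+ bp motif, guards and 30 bp of usable flank
    if n_events * slot + 2 * slot > genome_length:
        raise ValueError(
            f"infeasible density: {n_events} events need >= {(n_events + 2) * slot} bp, "
            f"got {genome_length}"
        )
    genome = list(rng.choice(list(_BASES), size=genome_length))

    order = ["SBS"] * n_sbs + ["DBS"] * n_dbs + ["ID"] * n_indels
    rng.shuffle(order)
    mutations: list[GenomicMutation] = []
    tallies = {
        name: dict.fromkeys(ClassificationSchema(name).classes, 0)
        for name in ("SBS96", "DBS78", "ID83")
    }

    def choose_not(exclude: set[str]) -> str:
        return str(rng.choice([b for b in _BASES if b not in exclude]))

    for i, etype in enumerate(order):
        start = slot + i * slot  # 0-based slot origin, guards margin at both ends
        centre = start + slot // 2
        if etype == "SBS":
            pos = centre  # 0-based
            ref = genome[pos]
            alt = choose_not({ref})
            ctx = "".join(genome[pos - 1 : pos + 2])
            tallies["SBS96"][_sbs_truth(ctx, alt)] += 1
            mutations.append(
                GenomicMutation(sample_id, chrom, pos + 1, ref, alt, MutationKind.SBS)
            )
        elif etype == "DBS":
            pos = centre
            ref2 = "".join(genome[pos : pos + 2])
            alt2 = choose_not({ref2[0]}) + choose_not({ref2[1]})
            tallies["DBS78"][_dbs_truth(ref2, alt2)] += 1
            mutations.append(
                GenomicMutation(sample_id, chrom, pos + 1, ref2, alt2, MutationKind.DBS)
            )
        else:
            mutations.append(
                _implant_indel(rng, genome, centre, sample_id, chrom, tallies["ID83"], choose_not)
            )

    seq = "".join(genome)
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "genome.fa")
    vcf_path = os.path.join(out_dir, f"{sample_id}.vcf")
    write_fasta(fasta_path, {chrom: seq})
    write_vcf(
        vcf_path,
        mutations,
        {chrom: genome_length},
        fetch=lambda c, s, e: seq[s:e],
    )
    truth = {
        name: pd.DataFrame({sample_id: pd.Series(t)}).reindex(
            list(ClassificationSchema(name).classes), fill_value=0
        )
        for name, t in tallies.items()
    }
    return SimulatedVariantData(
        fasta_path=fasta_path,
        vcf_path=vcf_path,
        sample_id=sample_id,
        mutations=mutations,
        truth=truth,
        genome={chrom: seq},
    )


def _implant_indel(rng, genome, centre, sample_id, chrom, tally, choose_not) -> GenomicMutation:
    """Overwrite a controlled motif window and return the indel record."""
    subtype = rng.choice(
        ["del1", "ins1", "del_rep", "ins_rep", "del_mh"],
    )
    pos0 = centre  # 0-based start of the structured window
    if subtype == "del1":
        b = str(rng.choice(list(_BASES)))
        run = int(rng.integers(1, 8))
        g1, g2 = choose_not({b}), choose_not({b})
        _write(genome, pos0, g1 + b * run + g2)
        pyr = b if b in "CT" else _COMP[b]
        tally[f"1:Del:{pyr}:{min(run - 1, 5)}"] += 1
        return GenomicMutation(sample_id, chrom, pos0 + 2, b, "", MutationKind.DEL)
    if subtype == "ins1":
        run = int(rng.integers(0, 7))
        b = str(rng.choice(list(_BASES)))
        g1, g2 = choose_not({b}), choose_not({b})
        _write(genome, pos0, g1 + b * max(run, 1) + g2 if run else g1 + g2)
        pyr = b if b in "CT" else _COMP[b]
        tally[f"1:Ins:{pyr}:{min(run, 5)}"] += 1
        # insertion lands just after g1, i.e. at the start of the run
        return GenomicMutation(sample_id, chrom, pos0 + 2, "", b, MutationKind.INS)
    L = int(rng.integers(2, 6))
    motif = choose_not(set())
    motif += "".join(str(rng.choice(list(_BASES))) for _ in range(L - 2))
    motif += choose_not({motif[0]})  # first != last: runs cannot merge
    size = min(L, 5)
    if subtype == "del_rep":
        copies = int(rng.integers(1, 8))
        g1 = choose_not({motif[-1]})
        g2 = choose_not({motif[0]})
        _write(genome, pos0, g1 + motif * copies + g2)
        tally[f"{size}:Del:R:{min(copies - 1, 5)}"] += 1
        return GenomicMutation(sample_id, chrom, pos0 + 2, motif, "", MutationKind.DEL)
    if subtype == "ins_rep":
        copies = int(rng.integers(0, 7))
        g1 = choose_not({motif[-1]})
        g2 = choose_not({motif[0]})
        _write(genome, pos0, g1 + motif * max(copies, 1) + g2 if copies else g1 + g2)
        tally[f"{size}:Ins:R:{min(copies, 5)}"] += 1
        return GenomicMutation(sample_id, chrom, pos0 + 2, "", motif, MutationKind.INS)
    # deletion with flanking microhomology: single copy, right flank shares
    # the motif's first mh bases, guards stop any further match
    mh = int(rng.integers(1, L))
    g1 = choose_not({motif[-1]})
    g2 = choose_not({motif[mh], motif[0]})
    _write(genome, pos0, g1 + motif + motif[:mh] + g2)
    cap = {2: 1, 3: 2, 4: 3, 5: 5}[size]
    tally[f"{size}:Del:M:{min(mh, cap)}"] += 1
    return GenomicMutation(sample_id, chrom, pos0 + 2, motif, "", MutationKind.DEL)


def _write(genome: list, pos0: int, block: str) -> None:
    genome[pos0 : pos0 + len(block)] = list(block)


def rescale(scenario: SimulationScenario, n_samples: int) -> SimulationScenario:
    """Copy of a scenario with a different cohort size (seed preserved)."""
    return replace(scenario, n_samples=n_samples)
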