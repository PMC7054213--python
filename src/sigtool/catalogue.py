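"""Mutation classification schemes and catalogue construction.

Somatic mutations are classified into the community-standard schemes used
for mutational-signature analysis:

* **SBS96** — single-base substitutions in trinucleotide context.  Each
  substitution is represented by the pyrimidine of the mutated base pair
  (purine mutations are reverse-complemented), giving 6 substitution types
  (C>A, C>G, C>T, T>A, T>C, T>G) x 4 5' bases x 4 3' bases = 96 classes.
* **SBS1536** — the same convention with two flanking bases on each side
  (pentanucleotide context), 6 x 16 x 16 = 1,536 classes.
* **SBS192** — SBS96 restricted to transcribed genomic regions and split by
  whether the mutated pyrimidine lies on the transcribed (template) or
  untranscribed (coding) strand of the covering gene, 2 x 96 = 192 classes.
* **DBS78** — doublet-base substitutions collapsed over reverse
  complements, 78 classes.
* **ID83** — small insertions and deletions classified by event size,
  repeat context and flanking microhomology, 83 classes.

A :class:`MutationCatalogue` is the classes-by-samples matrix of
nonnegative integer counts under one of these schemes, the input V of the
nonnegative matrix factorisations in :mod:`sigtool.extraction`.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


class MutationKind(str, Enum):
    SBS = "SBS"
    DBS = "DBS"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class GenomicMutation:
    """One somatic variant in minimal, already-normalised form.

    ``pos`` is 1-based and points at the first reference base of the event;
    for insertions it is the reference position at which the inserted
    sequence begins (the insertion falls between ``pos - 1`` and ``pos``).
    For insertions ``ref`` is empty; for deletions ``alt`` is empty; the
    VCF anchor base must already have been stripped (see
    :func:`normalise_alleles`).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: MutationKind

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")


class StrandAnnotation:
    """Strand-resolved transcribed regions (BED convention: 0-based, half-open).

    Intervals on the same strand are merged; a genomic position is assigned
    a unique gene strand only when covered by exactly one strand.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, start, end, strand in intervals:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_key.setdefault((chrom, strand), []).append((start, end))
        self._index: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        for key, ivs in by_key.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._index[key] = ([s for s, _ in merged], [e for _, e in merged])

    @classmethod
    def from_bed(cls, path: str) -> "StrandAnnotation":
        """Load from a BED file with at least chrom/start/end/name/score/strand."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ValueError("BED line lacks a strand column: " + line.strip())
                ivs.append((parts[0], int(parts[1]), int(parts[2]), parts[5]))
        return cls(ivs)

    def _covers(self, chrom: str, pos0: int, strand: str) -> bool:
        key = (chrom, strand)
        if key not in self._index:
            return False
        starts, ends = self._index[key]
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]

    def gene_strand(self, chrom: str, pos: int) -> str | None:
        """Unique gene strand covering 1-based ``pos``, else None (ambiguous/intergenic)."""
        pos0 = pos - 1
        plus = self._covers(chrom, pos0, "+")
        minus = self._covers(chrom, pos0, "-")
        if plus == minus:
            return None
        return "+" if plus else "-"


# ---------------------------------------------------------------------------
# schema enumeration
# ---------------------------------------------------------------------------

def _sbs_labels(flank: int) -> list[str]:
    ctx = ["".join(p) for p in _kmers(flank)]
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_TYPES
        for five in ctx
        for three in ctx
    ]


def _kmers(k: int) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = [()]
    for _ in range(k):
        out = [p + (b,) for p in out for b in BASES]
    return out


def _dbs_canonical(ref2: str, alt2: str) -> str:
    """Canonical label of a doublet substitution under reverse-complement collapse.

    Of ``(ref, alt)`` and ``(revcomp(ref), revcomp(alt))``, keep the pair
    whose ref 2-mer sorts first; for palindromic refs keep the smaller alt.
    """
    rr, ra = revcomp(ref2), revcomp(alt2)
    if (rr, ra) < (ref2, alt2):
        ref2, alt2 = rr, ra
    return f"{ref2}>{alt2}"


def _dbs_labels() -> list[str]:
    labels = {
        _dbs_canonical(r, a)
        for r in ("".join(p) for p in _kmers(2))
        for a in ("".join(p) for p in _kmers(2))
        if a[0] != r[0] and a[1] != r[1]
    }
    return sorted(labels)


def _id_labels() -> list[str]:
    labels = []
    # 1 bp deletions/insertions at mono-nucleotide repeats; the numeric field
    # counts repeat units besides the event itself (COSMIC convention), so
    # "1:Del:C:0" is a C deleted from a homopolymer of total length 1.
    for base in "CT":
        labels += [f"1:Del:{base}:{n}" for n in range(6)]
    for base in "CT":
        labels += [f"1:Ins:{base}:{n}" for n in range(6)]
    for size in (2, 3, 4, 5):  # 5 == 5+
        labels += [f"{size}:Del:R:{n}" for n in range(6)]
    for size in (2, 3, 4, 5):
        labels += [f"{size}:Ins:R:{n}" for n in range(6)]
    mh_bins = {2: 1, 3: 2, 4: 3, 5: 5}
    for size in (2, 3, 4, 5):
        labels += [f"{size}:Del:M:{m}" for m in range(1, mh_bins[size] + 1)]
    return labels


_SCHEMA_BUILDERS = {
    "SBS96": lambda: _sbs_labels(1),
    "SBS192": lambda: [f"{s}:{lab}" for s in ("Transcribed", "Untranscribed") for lab in _sbs_labels(1)],
    "SBS1536": lambda: _sbs_labels(2),
    "DBS78": _dbs_labels,
    "ID83": _id_labels,
}

SCHEMA_SIZES = {"SBS96": 96, "SBS192": 192, "SBS1536": 1536, "DBS78": 78, "ID83": 83}


@lru_cache(maxsize=None)
def enumerate_classes(schema_name: str) -> tuple[str, ...]:
    """Return the canonical ordered class labels of a classification scheme."""
    try:
        labels = tuple(_SCHEMA_BUILDERS[schema_name]())
    except KeyError:
        raise ValueError(
            f"unknown schema {schema_name!r}; expected one of {sorted(_SCHEMA_BUILDERS)}"
        ) from None
    assert len(labels) == SCHEMA_SIZES[schema_name]
    return labels


@dataclass(frozen=True)
class ClassificationSchema:
    name: str
    classes: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "classes", enumerate_classes(self.name))

    def __len__(self) -> int:
        return len(self.classes)


# ---------------------------------------------------------------------------
# per-mutation classification
# ---------------------------------------------------------------------------

def _check_dna(seq: str, what: str) -> None:
    if not seq or any(b not in BASES for b in seq):
        raise ValueError(f"{what} contains non-ACGT characters: {seq!r}")


def classify_sbs(ref: str, alt: str, context: str, flank: int = 1) -> str:
    """SBS96 (flank=1) or SBS1536 (flank=2) label of a single-base substitution.

    ``context`` is the reference sequence centred on the mutated base with
    ``flank`` bases on each side; purine-reference mutations are
    reverse-complemented so that the pyrimidine of the pair is reported.
    """
    if flank not in (1, 2):
        raise ValueError("flank must be 1 or 2")
    _check_dna(context, "context")
    _check_dna(ref, "ref")
    _check_dna(alt, "alt")
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if len(context) != 2 * flank + 1:
        raise ValueError(f"context length {len(context)} != {2 * flank + 1}")
    if context[flank] != ref:
        raise ValueError(f"context centre {context[flank]} does not match ref {ref}")
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{context[:flank]}[{ref}>{alt}]{context[flank + 1:]}"


def classify_sbs_stranded(
    mut: GenomicMutation, context: str, annotation: StrandAnnotation
) -> str | None:
    """SBS192 label, or None for intergenic / strand-ambiguous positions.

    The mutation is "Transcribed" when the pyrimidine of the mutated pair
    lies on the template (transcribed) strand of the covering gene — i.e.
    when the pyrimidine strand is the opposite of the gene's coding strand —
    and "Untranscribed" otherwise.
    """
    base = classify_sbs(mut.ref, mut.alt, context, flank=1)
    gene_strand = annotation.gene_strand(mut.chrom, mut.pos)
    if gene_strand is None:
        return None
    pyrimidine_strand = "+" if mut.ref in PYRIMIDINES else "-"
    label = "Transcribed" if pyrimidine_strand != gene_strand else "Untranscribed"
    return f"{label}:{base}"


def classify_dbs(ref2: str, alt2: str) -> str:
    """DBS78 label of a doublet substitution (reverse-complement collapsed)."""
    _check_dna(ref2, "ref")
    _check_dna(alt2, "alt")
    if len(ref2) != 2 or len(alt2) != 2:
        raise ValueError("doublet alleles must have length 2")
    if ref2 == alt2:
        raise ValueError("ref equals alt")
    if ref2[0] == alt2[0] or ref2[1] == alt2[1]:
        raise ValueError(f"{ref2}>{alt2} is not a true doublet: a base is shared")
    return _dbs_canonical(ref2, alt2)


def _run_length(seq: str, base: str) -> int:
    n = 0
    for b in seq:
        if b != base:
            break
        n += 1
    return n


def _copies(seq: str, motif: str) -> int:
    n = 0
    L = len(motif)
    while seq[n * L : (n + 1) * L] == motif:
        n += 1
    return n


def classify_indel(kind: MutationKind, motif: str, left: str, right: str) -> str:
    """ID83 label of an insertion or deletion.

    ``motif`` is the inserted/deleted sequence; ``left`` and ``right`` are
    the flanking reference sequences immediately adjacent to the event (for
    deletions the deleted bases themselves are excluded), each at least
    six motif lengths long.  The classification is invariant under
    left-normalisation: repeat-unit counts and microhomology lengths do not
    change when an indel is shifted within its repeat tract.
    """
    if kind not in (MutationKind.INS, MutationKind.DEL):
        raise ValueError("classify_indel expects an INS or DEL mutation")
    _check_dna(motif, "indel motif")
    L = len(motif)
    if len(left) < 6 * L or len(right) < 6 * L:
        raise ValueError(
            f"flanking sequence too short: need >= {6 * L} bases on each side"
        )
    _check_dna(left[-6 * L :], "left flank")
    _check_dna(right[: 6 * L], "right flank")
    is_del = kind is MutationKind.DEL
    size = min(L, 5)

    if L == 1:
        base = motif
        run = _run_length(left[::-1], base) + _run_length(right, base)
        if is_del:
            run += 1  # homopolymer length includes the deleted base
            if base in "AG":
                base = revcomp(base)
            return f"1:Del:{base}:{min(run - 1, 5)}"
        run = max(_run_length(left[::-1], base), _run_length(right, base))
        if base in "AG":
            base = revcomp(base)
        return f"1:Ins:{base}:{min(run, 5)}"

    # tandem copies of the motif adjacent to the event in the reference
    left_copies = _copies(left[::-1], motif[::-1])
    right_copies = _copies(right, motif)
    copies = left_copies + right_copies
    if is_del:
        total = copies + 1  # include the deleted copy
        if total >= 2:
            return f"{size}:Del:R:{min(total - 1, 5)}"
        # single copy: scan for microhomology between the deleted motif and
        # its flanks (longest prefix of the motif matching the following
        # sequence, longest suffix matching the preceding one; max of both)
        mh_right = 0
        while mh_right < L - 1 and right[mh_right] == motif[mh_right]:
            mh_right += 1
        mh_left = 0
        while mh_left < L - 1 and left[-1 - mh_left] == motif[-1 - mh_left]:
            mh_left += 1
        mh = max(mh_left, mh_right)
        if mh == 0:
            return f"{size}:Del:R:0"
        mh_cap = {2: 1, 3: 2, 4: 3, 5: 5}[size]
        return f"{size}:Del:M:{min(mh, mh_cap)}"
    return f"{size}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# allele normalisation
# ---------------------------------------------------------------------------

def normalise_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix from a VCF-style (pos, ref, alt).

    After trimming, an insertion has empty ``ref`` and a deletion empty
    ``alt``; ``pos`` points at the first event base (for insertions, the
    base left of the insertion point, VCF-style).
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def mutation_kind(ref: str, alt: str) -> MutationKind | None:
    if len(ref) == 1 and len(alt) == 1:
        return MutationKind.SBS
    if len(ref) == 2 and len(alt) == 2 and ref[0] != alt[0] and ref[1] != alt[1]:
        return MutationKind.DBS
    if len(ref) == 0 and len(alt) > 0:
        return MutationKind.INS
    if len(alt) == 0 and len(ref) > 0:
        return MutationKind.DEL
    return None


def left_normalise(mut: GenomicMutation, fetch) -> GenomicMutation:
    """Shift an indel to its leftmost equivalent position.

    ``fetch(chrom, start, end)`` returns the reference sequence for the
    0-based half-open interval.
    """
    if mut.kind not in (MutationKind.INS, MutationKind.DEL):
        return mut
    motif = mut.ref if mut.kind is MutationKind.DEL else mut.alt
    pos = mut.pos
    motif = list(motif)
    while pos > 1:
        prev = fetch(mut.chrom, pos - 2, pos - 1)
        if not prev or prev != motif[-1]:
            break
        motif = [prev] + motif[:-1]
        pos -= 1
    motif_s = "".join(motif)
    if mut.kind is MutationKind.DEL:
        return GenomicMutation(mut.sample_id, mut.chrom, pos, motif_s, "", mut.kind)
    return GenomicMutation(mut.sample_id, mut.chrom, pos, "", motif_s, mut.kind)


# ---------------------------------------------------------------------------
# catalogue container and construction
# ---------------------------------------------------------------------------

@dataclass
class MutationCatalogue:
    """Classes-by-samples matrix of nonnegative integer mutation counts."""

    schema: ClassificationSchema
    counts: pd.DataFrame  # index = class labels (canonical order), columns = samples

    def __post_init__(self):
        expected = list(self.schema.classes)
        if list(self.counts.index) != expected:
            self.counts = self.counts.reindex(expected, fill_value=0)
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("catalogue contains negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def to_csv(self, path: str) -> None:
        self.counts.rename_axis("MutationType").to_csv(path)

    @classmethod
    def from_csv(cls, path: str, schema_name: str | None = None) -> "MutationCatalogue":
        df = pd.read_csv(path, index_col=0)
        df.index.name = None
        if schema_name is None:
            schema_name = _infer_schema(len(df))
        return cls(ClassificationSchema(schema_name), df)


def _infer_schema(n_classes: int) -> str:
    for name, size in SCHEMA_SIZES.items():
        if size == n_classes:
            return name
    raise ValueError(f"cannot infer schema from {n_classes} classes")


@dataclass
class SkipRecord:
    sample_id: str
    chrom: str
    pos: int
    reason: str


class ReferenceMismatch(ValueError):
    pass


def _fetcher(reference) -> "callable":
    """Adapt a pyfaidx.Fasta (or a plain dict of str) to fetch(chrom, start, end)."""
    if isinstance(reference, Mapping):
        def fetch(chrom, start, end):
            seq = reference[chrom]
            if start < 0 or end > len(seq):
                return ""
            return str(seq[start:end]).upper()
        return fetch

    def fetch(chrom, start, end):
        if start < 0:
            return ""
        return str(reference[chrom][start:end]).upper()

    return fetch


def build_catalogue(
    mutations: Sequence[GenomicMutation],
    reference,
    schema_name: str,
    annotation: StrandAnnotation | None = None,
    samples: Sequence[str] | None = None,
) -> tuple[MutationCatalogue, list[SkipRecord]]:
    """Classify mutations and tally them into a catalogue matrix.

    ``reference`` is a ``pyfaidx.Fasta`` handle or a dict of chromosome
    sequences.  Returns the catalogue and a skip log explaining every
    mutation excluded (wrong kind for the schema, N in alleles, no unique
    strand for SBS192, ...).  Reference-mismatching SBS/DBS/DEL records
    raise :class:`ReferenceMismatch`.
    """
    schema = ClassificationSchema(schema_name)
    classes = {lab: i for i, lab in enumerate(schema.classes)}
    fetch = _fetcher(reference)
    if samples is None:
        sample_list = sorted({m.sample_id for m in mutations})
    else:
        sample_list = list(samples)
        declared = set(sample_list)
        for m in mutations:
            if m.sample_id not in declared:
                raise ValueError(f"sample {m.sample_id!r} not in declared sample list")
    col = {s: j for j, s in enumerate(sample_list)}
    counts = np.zeros((len(schema), len(sample_list)), dtype=int)
    skipped: list[SkipRecord] = []
    flank = 2 if schema_name == "SBS1536" else 1

    def skip(m: GenomicMutation, reason: str) -> None:
        skipped.append(SkipRecord(m.sample_id, m.chrom, m.pos, reason))

    wanted_kinds = {
        "SBS96": {MutationKind.SBS},
        "SBS192": {MutationKind.SBS},
        "SBS1536": {MutationKind.SBS},
        "DBS78": {MutationKind.DBS},
        "ID83": {MutationKind.INS, MutationKind.DEL},
    }[schema_name]

    for m in mutations:
        if any(b not in BASES for b in m.ref + m.alt):
            skip(m, "non-ACGT allele")
            continue
        if m.kind not in wanted_kinds:
            skip(m, f"wrong mutation kind {m.kind.value} for schema {schema_name}")
            continue
        try:
            if m.kind is MutationKind.SBS:
                ctx = fetch(m.chrom, m.pos - 1 - flank, m.pos + flank)
                if len(ctx) != 2 * flank + 1:
                    skip(m, "context out of reference bounds")
                    continue
                if ctx[flank] != m.ref:
                    raise ReferenceMismatch(
                        f"reference base {ctx[flank]} != ref allele {m.ref} at {m.chrom}:{m.pos}"
                    )
                if "N" in ctx:
                    skip(m, "N in context")
                    continue
                if schema_name == "SBS192":
                    label = classify_sbs_stranded(m, ctx, annotation or StrandAnnotation([]))
                    if label is None:
                        skip(m, "no unique transcribed strand")
                        continue
                else:
                    label = classify_sbs(m.ref, m.alt, ctx, flank=flank)
            elif m.kind is MutationKind.DBS:
                ref2 = fetch(m.chrom, m.pos - 1, m.pos + 1)
                if ref2 != m.ref:
                    raise ReferenceMismatch(
                        f"reference doublet {ref2} != ref allele {m.ref} at {m.chrom}:{m.pos}"
                    )
                label = classify_dbs(m.ref, m.alt)
            else:  # indel
                mm = left_normalise(m, fetch)
                motif = mm.ref if mm.kind is MutationKind.DEL else mm.alt
                need = 6 * len(motif)
                if mm.kind is MutationKind.DEL:
                    here = fetch(mm.chrom, mm.pos - 1, mm.pos - 1 + len(motif))
                    if here != motif:
                        raise ReferenceMismatch(
                            f"reference {here} != deleted allele {motif} at {mm.chrom}:{mm.pos}"
                        )
                    left = fetch(mm.chrom, mm.pos - 1 - need, mm.pos - 1)
                    right = fetch(mm.chrom, mm.pos - 1 + len(motif), mm.pos - 1 + len(motif) + need)
                else:
                    left = fetch(mm.chrom, mm.pos - 1 - need, mm.pos - 1)
                    right = fetch(mm.chrom, mm.pos - 1, mm.pos - 1 + need)
                if len(left) < need or len(right) < need:
                    skip(m, "indel too close to reference edge")
                    continue
                if "N" in left or "N" in right:
                    skip(m, "N in flanking sequence")
                    continue
                label = classify_indel(mm.kind, motif, left, right)
        except ReferenceMismatch:
            raise
        except ValueError as exc:
            skip(m, str(exc))
            continue
        counts[classes[label], col[m.sample_id]] += 1

    df = pd.DataFrame(counts, index=list(schema.classes), columns=sample_list)
    for rec in skipped:
        logger.debug("skipped %s %s:%d — %s", rec.sample_id, rec.chrom, rec.pos, rec.reason)
    return MutationCatalogue(schema, df), skipped
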