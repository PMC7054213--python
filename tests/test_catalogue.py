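"""Classification schemes and catalogue construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigtool.catalogue import (
    GenomicMutation,
    MutationKind,
    StrandAnnotation,
    build_catalogue,
    classify_dbs,
    classify_indel,
    classify_sbs,
    classify_sbs_stranded,
    enumerate_classes,
    left_normalise,
    normalise_alleles,
    revcomp,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# schema enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "schema,count",
    [("SBS96", 96), ("SBS192", 192), ("SBS1536", 1536), ("DBS78", 78), ("ID83", 83)],
)
def test_schema_class_counts(schema, count):
    labels = enumerate_classes(schema)
    assert len(labels) == count
    assert len(set(labels)) == count


def test_unknown_schema_rejected():
    with pytest.raises(ValueError, match="unknown schema"):
        enumerate_classes("SBS42")


def test_sbs1536_projects_16_to_1_onto_sbs96():
    """Dropping the outer context bases maps pentanucleotide labels onto
    trinucleotide labels surjectively, 16 per target."""
    counts = {}
    for label in enumerate_classes("SBS1536"):
        inner = label[1:-1]  # strip one outer base each side
        counts[inner] = counts.get(inner, 0) + 1
    assert set(counts) == set(enumerate_classes("SBS96"))
    assert all(v == 16 for v in counts.values())


def test_id83_microhomology_block_has_11_entries():
    mh = [lab for lab in enumerate_classes("ID83") if ":M:" in lab]
    assert len(mh) == 11  # 1 + 2 + 3 + 5 over deletion sizes 2,3,4,5+


# ---------------------------------------------------------------------------
# SBS classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,context,flank,expected",
    [
        ("C", "A", "ACA", 1, "A[C>A]A"),
        ("G", "A", "AGC", 1, "G[C>T]T"),
        ("G", "T", "TAGCA", 2, "TG[C>A]TA"),  # revcomp(TAGCA) = TGCTA
        ("T", "G", "TTT", 1, "T[T>G]T"),
        ("A", "C", "AAA", 1, "T[T>G]T"),
    ],
)
def test_classify_sbs_examples(ref, alt, context, flank, expected):
    assert classify_sbs(ref, alt, context, flank=flank) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    ctx=st.text(alphabet=BASES, min_size=3, max_size=3),
    alt=st.sampled_from(BASES),
)
def test_classify_sbs_strand_symmetry(ctx, alt):
    """The pyrimidine convention makes classification strand-symmetric."""
    ref = ctx[1]
    if alt == ref:
        alt = BASES[(BASES.index(alt) + 1) % 4]
    label = classify_sbs(ref, alt, ctx)
    mirrored = classify_sbs(revcomp(ref), revcomp(alt), revcomp(ctx))
    assert label == mirrored
    assert label in enumerate_classes("SBS96")


def test_classify_sbs_rejects_bad_input():
    with pytest.raises(ValueError, match="centre"):
        classify_sbs("C", "A", "AGA")
    with pytest.raises(ValueError, match="non-ACGT"):
        classify_sbs("C", "A", "ANA"[:3])
    with pytest.raises(ValueError, match="context length"):
        classify_sbs("C", "A", "ACAA")


# ---------------------------------------------------------------------------
# stranded classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def annotation():
    # + gene at [100, 200), - gene at [300, 400), both-strand overlap at [500, 600)
    return StrandAnnotation(
        [
            ("chr1", 100, 200, "+"),
            ("chr1", 300, 400, "-"),
            ("chr1", 500, 600, "+"),
            ("chr1", 500, 600, "-"),
        ]
    )


def test_stranded_pyrimidine_in_plus_gene_is_untranscribed(annotation):
    m = GenomicMutation("s", "chr1", 150, "C", "T", MutationKind.SBS)
    label = classify_sbs_stranded(m, "ACA", annotation)
    assert label.startswith("Untranscribed:")


def test_stranded_purine_in_plus_gene_is_transcribed(annotation):
    # purine ref means the pyrimidine partner sits on the - strand, which is
    # the template of a + gene
    m = GenomicMutation("s", "chr1", 150, "G", "A", MutationKind.SBS)
    label = classify_sbs_stranded(m, "AGC", annotation)
    assert label == "Transcribed:G[C>T]T"


@pytest.mark.parametrize("pos", [50, 550])  # intergenic; covered by both strands
def test_stranded_ambiguous_positions_return_none(annotation, pos):
    m = GenomicMutation("s", "chr1", pos, "C", "T", MutationKind.SBS)
    assert classify_sbs_stranded(m, "ACA", annotation) is None


# ---------------------------------------------------------------------------
# DBS classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ref,alt,expected",
    [("CC", "TT", "CC>TT"), ("GG", "AA", "CC>TT"), ("AT", "TG", "AT>CA")],
)
def test_classify_dbs_examples(ref, alt, expected):
    assert classify_dbs(ref, alt) == expected


def test_dbs_canonicalization_exhaustive():
    """All 144 raw doublets collapse onto exactly the 78 canonical classes,
    and both members of each reverse-complement pair map to the same label."""
    labels = set()
    n_raw = 0
    for ref in ("".join(p) for p in itertools.product(BASES, repeat=2)):
        for alt in ("".join(p) for p in itertools.product(BASES, repeat=2)):
            if alt[0] == ref[0] or alt[1] == ref[1]:
                continue
            n_raw += 1
            label = classify_dbs(ref, alt)
            assert label == classify_dbs(revcomp(ref), revcomp(alt))
            labels.add(label)
    assert n_raw == 144
    assert labels == set(enumerate_classes("DBS78"))


def test_classify_dbs_rejects_shared_base():
    with pytest.raises(ValueError, match="shared"):
        classify_dbs("AC", "AT")


# ---------------------------------------------------------------------------
# indel classification
# ---------------------------------------------------------------------------

def mh_oracle(motif: str, left: str, right: str) -> int:
    """Independent microhomology scan: longest shared prefix of the deleted
    motif with the following sequence, and suffix with the preceding one."""
    pre = next(
        (j for j in range(min(len(motif) - 1, len(right))) if right[j] != motif[j]),
        min(len(motif) - 1, len(right)),
    )
    suf = next(
        (
            j
            for j in range(min(len(motif) - 1, len(left)))
            if left[len(left) - 1 - j] != motif[len(motif) - 1 - j]
        ),
        min(len(motif) - 1, len(left)),
    )
    return max(pre, suf)


@pytest.mark.parametrize(
    "kind,motif,left,right,expected",
    [
        # delete one T from a run of exactly 5 Ts
        (MutationKind.DEL, "T", "GGTTTT", "GGGGGG", "1:Del:T:4"),
        # delete one A from a run of 3 As (A:T collapses to T)
        (MutationKind.DEL, "A", "GGGGAA", "CGGGGG", "1:Del:T:2"),
        # spec-style microhomology case: deleted TAGC, following TAGG
        (MutationKind.DEL, "TAGC", "G" * 24, "TAGG" + "C" * 20, "4:Del:M:3"),
        (MutationKind.INS, "T", "GGGGGG", "TTTGGG", "1:Ins:T:3"),
        (MutationKind.INS, "C", "AAAAAA", "AAAAAA", "1:Ins:C:0"),
        # 3-bp deletion of one copy: 2 copies left, 1 right, +1 deleted = 4
        (MutationKind.DEL, "ACG", "T" * 12 + "ACGACG", "ACG" + "T" * 15, "3:Del:R:3"),
    ],
)
def test_classify_indel_examples(kind, motif, left, right, expected):
    pad = 6 * len(motif)
    assert classify_indel(kind, motif, (left * pad)[-pad:], (right * pad)[:pad]) == expected


@settings(max_examples=150, deadline=None, derandomize=True)
@given(data=st.data())
def test_microhomology_agrees_with_scan_oracle(data):
    motif = data.draw(st.text(alphabet=BASES, min_size=2, max_size=5))
    left = data.draw(st.text(alphabet=BASES, min_size=6 * 5, max_size=6 * 5))
    right = data.draw(st.text(alphabet=BASES, min_size=6 * 5, max_size=6 * 5))
    label = classify_indel(MutationKind.DEL, motif, left, right)
    size = min(len(motif), 5)
    # the oracle adjudicates the single-copy (non-repeat) cases
    if f":Del:M:" in label or label == f"{size}:Del:R:0":
        mh = mh_oracle(motif, left, right)
        if mh == 0:
            assert label == f"{size}:Del:R:0"
        else:
            cap = {2: 1, 3: 2, 4: 3, 5: 5}[size]
            assert label == f"{size}:Del:M:{min(mh, cap)}"


def test_classify_indel_strand_symmetry_1bp():
    """Deleting an A and deleting a T from mirrored runs share the label."""
    a = classify_indel(MutationKind.DEL, "A", "G" * 10 + "AA", "G" * 12)
    t = classify_indel(MutationKind.DEL, "T", "C" * 12, "TT" + "C" * 10)
    assert a == t == "1:Del:T:2"


def test_classify_indel_flank_too_short():
    with pytest.raises(ValueError, match="too short"):
        classify_indel(MutationKind.DEL, "ACGT", "ACGTACG", "ACGTACG")


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (10, "CAG", "C", (11, "AG", "")),
        (10, "C", "CAG", (11, "", "AG")),
        (10, "CT", "CA", (11, "T", "A")),
        (10, "C", "A", (10, "C", "A")),
    ],
)
def test_normalise_alleles(pos, ref, alt, expected):
    assert normalise_alleles(pos, ref, alt) == expected


def test_left_normalise_shifts_deletion_to_run_start():
    seq = {"c": "GGGTTTTTAGG"}
    fetch = lambda chrom, s, e: seq[chrom][s:e]
    m = GenomicMutation("s", "c", 8, "T", "", MutationKind.DEL)  # last T of run
    shifted = left_normalise(m, fetch)
    assert shifted.pos == 4  # first T (1-based)


# ---------------------------------------------------------------------------
# catalogue construction
# ---------------------------------------------------------------------------

def test_build_catalogue_counts_and_conservation():
    ref = {"chr1": "AACATTGACGTACCTATTTTGACAGCTG" * 4}
    muts = [
        GenomicMutation("s1", "chr1", 4, "A", "C", MutationKind.SBS),
        GenomicMutation("s1", "chr1", 32, "A", "C", MutationKind.SBS),
        GenomicMutation("s1", "chr1", 60, "A", "C", MutationKind.SBS),
        GenomicMutation("s2", "chr1", 5, "T", "G", MutationKind.SBS),
        GenomicMutation("s2", "chr1", 17, "T", "", MutationKind.DEL),  # wrong kind
    ]
    cat, skipped = build_catalogue(muts, ref, "SBS96")
    # A>C in context CAT -> revcomp ATG, T>G: "A[T>G]G"
    assert cat.counts.loc["A[T>G]G", "s1"] == 3
    assert cat.counts["s1"].sum() == 3
    assert cat.counts["s2"].sum() == 1
    assert len(skipped) == 1 and "wrong mutation kind" in skipped[0].reason
    # conservation: cells + skips == inputs per sample
    assert cat.counts["s2"].sum() + 1 == 2


def test_build_catalogue_reference_mismatch_names_coordinate():
    ref = {"chr1": "AAAAAAAA"}
    muts = [GenomicMutation("s1", "chr1", 4, "C", "T", MutationKind.SBS)]
    with pytest.raises(ValueError, match="chr1:4"):
        build_catalogue(muts, ref, "SBS96")


def test_build_catalogue_undeclared_sample_rejected():
    ref = {"chr1": "AACAA"}
    muts = [GenomicMutation("sX", "chr1", 3, "C", "T", MutationKind.SBS)]
    with pytest.raises(ValueError, match="sX"):
        build_catalogue(muts, ref, "SBS96", samples=["s1"])


def test_generator_round_trip_exact(toy_genome):
    """Catalogues built from the simulated VCF equal the generation-time
    truth tallies exactly, for every schema."""
    from pyfaidx import Fasta

    from sigtool.io import read_vcf

    muts = read_vcf(toy_genome.vcf_path, sample_id=toy_genome.sample_id)
    ref = Fasta(toy_genome.fasta_path)
    for schema in ("SBS96", "DBS78", "ID83"):
        cat, _ = build_catalogue(muts, ref, schema, samples=[toy_genome.sample_id])
        truth = toy_genome.truth[schema]
        assert (cat.counts[toy_genome.sample_id].to_numpy() == truth[toy_genome.sample_id].to_numpy()).all()
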