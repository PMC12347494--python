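import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtmut.io_formats import GenomeSequence, MutationRecord
from rtmut.profiling import (
    CHANNEL_TRINUC,
    SBS96_INDEX,
    SBS96_LABELS,
    TRINUC32_INDEX,
    TRINUC32_LABELS,
    SBSProfile,
    TrinucFrequencies,
    build_indel_profile,
    build_sbs_profile,
    classify_indel,
    classify_sbs,
    count_trinucleotides,
    normalize_profile,
    reverse_complement,
)


def test_channel_scheme_shape():
    assert len(SBS96_LABELS) == 96
    assert len(set(SBS96_LABELS)) == 96
    # bijection: label -> index -> label
    for i, lab in enumerate(SBS96_LABELS):
        assert SBS96_INDEX[lab] == i
    # every channel's trinucleotide has the right middle base
    for i, lab in enumerate(SBS96_LABELS):
        tri = TRINUC32_LABELS[CHANNEL_TRINUC[i]]
        assert tri == lab[0] + lab[2] + lab[6]


@pytest.mark.parametrize(
    "seq, pos, ref, alt, expected",
    [
        ("ACAT", 2, "C", "T", "A[C>T]A"),  # pyrimidine reference, direct
        ("TGTA", 2, "G", "A", "A[C>T]A"),  # purine: revcomp context and substitution
        ("NCAT", 2, "C", "T", None),  # N in context
        ("ACAT", 1, "A", "T", None),  # chromosome edge: no 5' flank
        ("ACAT", 2, "G", "T", None),  # reference mismatch with genome
    ],
)
def test_classify_sbs(seq, pos, ref, alt, expected):
    g = GenomeSequence({"1": seq})
    rec = MutationRecord("1", pos, ref, alt, "SNV", "s")
    assert classify_sbs(rec, g) == expected


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_classify_strand_symmetry(seed):
    """Classification is invariant under reverse-complementing the genome."""
    rng = np.random.default_rng(seed)
    n = 50
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    g = GenomeSequence({"1": seq})
    g_rc = GenomeSequence({"1": reverse_complement(seq)})
    pos = int(rng.integers(2, n))
    ref = seq[pos - 1]
    alt = "ACGT"[int(rng.integers(0, 4))]
    if alt == ref:
        return
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rec = MutationRecord("1", pos, ref, alt, "SNV", "s")
    mirrored = MutationRecord("1", n - pos + 1, comp[ref], comp[alt], "SNV", "s")
    assert classify_sbs(rec, g) == classify_sbs(mirrored, g_rc)


def test_build_profile_empty_and_counts(toy_genome):
    prof = build_sbs_profile([], toy_genome, sample_id="s")
    assert prof.counts.sum() == 0 and prof.n_unclassified == 0
    recs = [MutationRecord("1", 2, "C", "T", "SNV", "s")] * 10
    prof = build_sbs_profile(recs, toy_genome)
    assert prof.counts[SBS96_INDEX["A[C>T]A"]] == 10
    assert prof.counts.sum() == 10


def test_build_profile_rejects_mixed_samples(toy_genome):
    recs = [
        MutationRecord("1", 2, "C", "T", "SNV", "s1"),
        MutationRecord("1", 4, "T", "A", "SNV", "s2"),
    ]
    with pytest.raises(ValueError, match="mixed sample"):
        build_sbs_profile(recs, toy_genome)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_profile_count_conservation(seed):
    """classified + unclassified always equals the number of SNVs supplied."""
    rng = np.random.default_rng(seed)
    seq = "".join("ACGTN"[i] for i in rng.choice(5, size=200, p=[0.24] * 4 + [0.04]))
    g = GenomeSequence({"1": seq})
    recs = []
    for _ in range(40):
        pos = int(rng.integers(1, 201))
        ref = seq[pos - 1] if rng.random() < 0.8 else "C"
        if ref == "N":
            ref = "C"
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        recs.append(MutationRecord("1", pos, ref, alt, "SNV", "s"))
    prof = build_sbs_profile(recs, g, sample_id="s")
    assert prof.counts.sum() + prof.n_unclassified == len(recs)


def test_count_trinucleotides_enumeration():
    g = GenomeSequence({"1": "ACAT"})
    tf = count_trinucleotides(g)
    expected = np.zeros(32)
    expected[TRINUC32_INDEX["ACA"]] = 1
    expected[TRINUC32_INDEX["ATG"]] = 1  # CAT collapses to ATG
    assert np.array_equal(tf.counts, expected)


def test_count_trinucleotides_all_a_collapses_to_ttt():
    g = GenomeSequence({"1": "A" * 10})
    tf = count_trinucleotides(g)
    assert tf.counts[TRINUC32_INDEX["TTT"]] == 8
    assert tf.counts.sum() == 8


def test_count_trinucleotides_regions():
    g = GenomeSequence({"1": "ACATACATACAT"})
    with pytest.raises(ValueError, match="empty region"):
        count_trinucleotides(g, regions={"1": []})
    # region shorter than 3 bp contributes nothing; valid region adds windows
    tf = count_trinucleotides(g, regions={"1": [(0, 2), (0, 5)]})
    assert tf.counts.sum() == 3  # windows ACA, CAT, ATA


def test_count_trinucleotides_window_conservation():
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    g = GenomeSequence({"1": seq})
    tf = count_trinucleotides(g, regions={"1": [(10, 200), (250, 400)]})
    assert tf.counts.sum() == (200 - 10 - 2) + (400 - 250 - 2)


def test_normalize_uniform_trinuc_preserves_shape(uniform_trinuc):
    counts = np.zeros(96, dtype=int)
    counts[0], counts[50] = 30, 10
    prof = SBSProfile(counts, "s")
    norm = normalize_profile(prof, uniform_trinuc)
    assert norm.freqs[0] == pytest.approx(0.75)
    assert norm.freqs[50] == pytest.approx(0.25)


def test_normalize_weights_by_trinucleotide():
    counts = np.zeros(96, dtype=int)
    counts[0] = 10  # A[C>A]A over trinuc ACA
    counts[1] = 10  # A[C>A]C over trinuc ACC
    tri = np.full(32, 1.0)
    tri[CHANNEL_TRINUC[0]] = 0.01
    tri[CHANNEL_TRINUC[1]] = 0.02
    norm = normalize_profile(SBSProfile(counts, "s"), TrinucFrequencies(tri))
    # weights 10/0.01 and 10/0.02 -> 2/3 and 1/3 (on trinuc proportions as given)
    tri_freqs = tri / tri.sum()
    w0, w1 = 10 / tri_freqs[CHANNEL_TRINUC[0]], 10 / tri_freqs[CHANNEL_TRINUC[1]]
    assert norm.freqs[0] == pytest.approx(w0 / (w0 + w1))
    assert norm.freqs[0] / norm.freqs[1] == pytest.approx(2.0)
    assert norm.freqs.sum() == pytest.approx(1.0, abs=1e-12)


def test_normalize_single_channel_and_errors(uniform_trinuc):
    counts = np.zeros(96, dtype=int)
    counts[42] = 7
    norm = normalize_profile(SBSProfile(counts, "s"), uniform_trinuc)
    assert norm.freqs[42] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="empty profile"):
        normalize_profile(SBSProfile(np.zeros(96, dtype=int), "s"), uniform_trinuc)
    tri = np.ones(32)
    tri[CHANNEL_TRINUC[42]] = 0.0
    with pytest.raises(ValueError, match=SBS96_LABELS[42].replace("[", r"\[").replace(">", ">")):
        normalize_profile(SBSProfile(counts, "s"), TrinucFrequencies(tri))


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_normalized_profiles_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 50, size=96)
    if counts.sum() == 0:
        counts[0] = 1
    tri = rng.uniform(0.5, 2.0, size=32)
    norm = normalize_profile(SBSProfile(counts, "s"), TrinucFrequencies(tri))
    assert norm.freqs.sum() == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "seq, rec, expected",
    [
        # 1-bp deletion of T inside TTTT run -> T homopolymer length 4
        ("ACTTTTGA", ("DEL", 4, "T", "-"), "DEL_T_hp4"),
        # 2-bp deletion -> long-deletion class
        ("ACTTTTGA", ("DEL", 4, "TT", "-"), "DEL_2-4bp"),
        # deletion of G in GGG run collapses to C-homopolymer
        ("AGGGTA", ("DEL", 3, "G", "-"), "DEL_C_hp3"),
        # insertion of T next to TTTT extends the run to length 5
        ("ACTTTTGA", ("INS", 4, "-", "T"), "INS_T_hp5"),
        # long insertion
        ("ACTTTTGA", ("INS", 4, "-", "GTGTG"), "INS_5+bp"),
    ],
)
def test_classify_indel(seq, rec, expected):
    g = GenomeSequence({"1": seq})
    vclass, pos, ref, alt = rec
    record = MutationRecord("1", pos, ref, alt, vclass, "s")
    assert classify_indel(record, g) == expected


def test_indel_profile_conservation(toy_genome):
    recs = [
        MutationRecord("1", 13, "T", "-", "DEL", "s"),
        MutationRecord("1", 17, "G", "-", "DEL", "s"),
        MutationRecord("1", 5, "-", "GG", "INS", "s"),
    ]
    prof = build_indel_profile(recs, toy_genome)
    assert prof.counts.sum() + prof.n_unclassified == len(recs)
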