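import numpy as np
import pytest
from scipy import stats as sps

from rtmut.profiling import SBS96_INDEX, build_sbs_profile
from rtmut.rt_partition import median_split
from rtmut.synthetic import (
    MutationPlacer,
    SyntheticCohortSpec,
    SyntheticEffect,
    SyntheticGenomeSpec,
    cohort_spec_from_dict,
    default_spectrum,
    generate_cohort,
    generate_genome,
    generate_sample,
)


@pytest.fixture(scope="module")
def genome_setup():
    spec = SyntheticGenomeSpec(n_chromosomes=2, chrom_length=200_000)
    genome, track = generate_genome(spec, np.random.default_rng(0))
    part = median_split(track)
    placer = MutationPlacer(genome, part)
    return genome, track, part, placer


def test_genome_deterministic():
    spec = SyntheticGenomeSpec(n_chromosomes=1, chrom_length=50_000)
    g1, t1 = generate_genome(spec, np.random.default_rng(5))
    g2, t2 = generate_genome(spec, np.random.default_rng(5))
    assert g1.sequence("1") == g2.sequence("1")
    assert t1.bins.equals(t2.bins)


def test_genome_base_composition():
    probs = (0.295, 0.205, 0.205, 0.295)
    spec = SyntheticGenomeSpec(n_chromosomes=1, chrom_length=300_000, base_probs=probs)
    g, _ = generate_genome(spec, np.random.default_rng(1))
    seq = g.sequence("1")
    n = len(seq)
    for base, p in zip("ACGT", probs):
        obs = seq.count(base) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) < 3.5 * se


def test_rt_track_covers_genome_once(genome_setup):
    genome, track, _, _ = genome_setup
    for chrom in genome.chroms:
        sub = track.bins[track.bins["chrom"] == chrom]
        assert sub["start"].iloc[0] == 0
        assert sub["end"].iloc[-1] == genome.length(chrom)
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()


def test_spec_validation():
    with pytest.raises(ValueError, match="multiple of the bin width"):
        SyntheticGenomeSpec(chrom_length=15_000, rt_bin_width=10_000)
    with pytest.raises(ValueError, match="collision"):
        SyntheticCohortSpec(effects=[("a", SyntheticEffect()), ("a", SyntheticEffect())])
    with pytest.raises(ValueError):
        SyntheticEffect(burden_fold=0)


def test_effect_spectrum_shift_mass():
    eff = SyntheticEffect(spectrum_shift={"A[C>T]A": 0.25})
    q = default_spectrum()
    shifted = eff.apply_to_spectrum(q)
    idx = SBS96_INDEX["A[C>T]A"]
    assert shifted.sum() == pytest.approx(1.0)
    assert shifted[idx] == pytest.approx(0.75 * q[idx] + 0.25)


def test_reference_alleles_match_genome(genome_setup):
    genome, _, part, placer = genome_setup
    recs = generate_sample(
        genome, part, placer, default_spectrum(), 500.0, 2.0,
        np.random.default_rng(2), "s", indel_burden=30.0,
    )
    assert len(recs) > 0
    for r in recs:
        if r.vclass in ("SNV", "DEL"):
            assert genome.sequence(r.chrom)[r.pos - 1 : r.pos - 1 + len(r.ref)] == r.ref


def test_late_early_burden_ratio(genome_setup):
    genome, _, part, placer = genome_setup
    ratio = 2.0
    rng = np.random.default_rng(3)
    recs = []
    for i in range(6):
        recs += generate_sample(
            genome, part, placer, default_spectrum(), 2000.0, ratio, rng, f"s{i}"
        )
    early = sum(part.assign_position(r.chrom, r.pos) == "early" for r in recs)
    late = sum(part.assign_position(r.chrom, r.pos) == "late" for r in recs)
    expected_late_frac = (part.late_bp * ratio) / (part.late_bp * ratio + part.early_bp)
    n = early + late
    se = np.sqrt(expected_late_frac * (1 - expected_late_frac) / n)
    assert abs(late / n - expected_late_frac) < 4 * se


def test_ratio_one_equal_per_bp_rates(genome_setup):
    genome, _, part, placer = genome_setup
    rng = np.random.default_rng(4)
    recs = []
    for i in range(6):
        recs += generate_sample(
            genome, part, placer, default_spectrum(), 2000.0, 1.0, rng, f"s{i}"
        )
    early = sum(part.assign_position(r.chrom, r.pos) == "early" for r in recs)
    late = len(recs) - early
    rate_e = early / part.early_bp
    rate_l = late / part.late_bp
    # binomial MC error on the pooled per-bp rate difference
    p = len(recs) / (part.early_bp + part.late_bp)
    se = np.sqrt(p / part.early_bp + p / part.late_bp)
    assert abs(rate_e - rate_l) < 4 * se


def test_late_restricted_shift_only_alters_late_profile(genome_setup):
    genome, _, part, placer = genome_setup
    eff = SyntheticEffect(spectrum_shift={"A[C>T]A": 0.3}, rt_restriction="late")
    rng = np.random.default_rng(5)
    recs = generate_sample(
        genome, part, placer, default_spectrum(), 6000.0, 1.0, rng, "s", effect=eff
    )
    by_state = {"early": [], "late": []}
    for r in recs:
        s = part.assign_position(r.chrom, r.pos)
        if s:
            by_state[s].append(r)
    idx = SBS96_INDEX["A[C>T]A"]
    q0 = default_spectrum()[idx]
    for state, expect_shift in (("early", False), ("late", True)):
        prof = build_sbs_profile(by_state[state], genome, rt_state=state, sample_id="s")
        freq = prof.counts[idx] / prof.counts.sum()
        if expect_shift:
            assert freq > q0 + 0.15
        else:
            se = np.sqrt(q0 * (1 - q0) / prof.counts.sum())
            assert abs(freq - q0) < 5 * se


def test_null_effect_sample_distributionally_identical(genome_setup):
    """burden_fold=1 with empty shift draws from the control distribution."""
    genome, _, part, placer = genome_setup
    rng = np.random.default_rng(6)
    null_eff = SyntheticEffect(burden_fold=1.0)
    a = generate_sample(genome, part, placer, default_spectrum(), 4000.0, 2.0, rng, "a")
    b = generate_sample(
        genome, part, placer, default_spectrum(), 4000.0, 2.0, rng, "b", effect=null_eff
    )
    pa = build_sbs_profile(a, genome, sample_id="a")
    pb = build_sbs_profile(b, genome, sample_id="b")
    channels_a = np.repeat(np.arange(96), pa.counts)
    channels_b = np.repeat(np.arange(96), pb.counts)
    res = sps.ks_2samp(channels_a, channels_b)
    assert res.pvalue >= 0.01


def test_cohort_generation_counts_and_manifest(tmp_path):
    spec = SyntheticCohortSpec(
        genome=SyntheticGenomeSpec(n_chromosomes=1, chrom_length=100_000),
        n_controls=4, n_replicates=2, baseline_burden=200.0, indel_burden=10.0,
        seed=11,
        effects=[("g1", SyntheticEffect()), ("g2", SyntheticEffect()),
                 ("g3", SyntheticEffect())],
    )
    outdir = tmp_path / "ds"
    cohort = generate_cohort(spec, outdir=outdir)
    assert len(cohort.records) == 4 + 3 * 2
    assert len(list((outdir / "maf").glob("*.maf"))) == 10
    assert (outdir / "manifest.json").exists()
    # regeneration from the stored spec is byte-identical
    import json

    manifest = json.loads((outdir / "manifest.json").read_text())
    spec2 = cohort_spec_from_dict(
        {k: v for k, v in manifest["spec"].items() if k != "control_group"}
        | {"control_group": manifest["control_group"]}
    )
    cohort2 = generate_cohort(spec2)
    assert cohort.records == cohort2.records


def test_cohort_sample_records_unique_positions(small_cohort):
    for sid, recs in small_cohort.records.items():
        keys = [(r.chrom, r.pos) for r in recs]
        assert len(set(keys)) == len(keys)
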