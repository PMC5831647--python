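"""Generator contracts: determinism, bounds, planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest

from metaorigin import (
    ConditionModifiers,
    ExpressionEffectModel,
    FactorOccupancyModel,
    FiberModel,
    SyntheticGenomeSpec,
    compute_enrichment,
    expected_coverage,
    fit_decay_scale,
    simulate_chip,
    simulate_chip_pair,
    simulate_expression,
    simulate_fibers,
    simulate_genome,
    simulate_input,
)


def small_spec(**kw):
    defaults = dict(
        chrom_lengths={"chr1": 2_000_000},
        origins={"chr1": [1_000_000]},
        seed=7,
    )
    defaults.update(kw)
    return SyntheticGenomeSpec(**defaults)


def test_genome_deterministic_for_fixed_seed(tmp_path):
    a = simulate_genome(small_spec())
    b = simulate_genome(small_spec())
    pd.testing.assert_frame_equal(a.genes, b.genes)
    pd.testing.assert_frame_equal(a.elements, b.elements)
    a.write_bed(tmp_path / "x1") if (tmp_path / "x1").mkdir() is None else None
    b.write_bed(tmp_path / "x2") if (tmp_path / "x2").mkdir() is None else None
    for name in ("origins.bed", "genes.bed", "elements.bed"):
        assert (tmp_path / "x1" / name).read_bytes() == (tmp_path / "x2" / name).read_bytes()


def test_zero_origins_allowed():
    bundle = simulate_genome(small_spec(origins={"chr1": []}))
    assert len(bundle.origin_set()) == 0


def test_origin_bounds_enforced_and_scanned():
    with pytest.raises(ValueError, match="closer than"):
        simulate_genome(small_spec(origins={"chr1": [50_000]}))
    with pytest.raises(ValueError, match="outside"):
        simulate_genome(small_spec(origins={"chr1": [5_000_000]}))
    # 2 chromosomes, 10 origins: every emitted coordinate within bounds
    spec = small_spec(
        chrom_lengths={"chr1": 2_000_000, "chr2": 3_000_000},
        origins={
            "chr1": [300_000, 700_000, 1_100_000, 1_500_000],
            "chr2": [400_000, 800_000, 1_200_000, 1_600_000, 2_000_000, 2_400_000],
        },
    )
    bundle = simulate_genome(spec)
    for df in (bundle.origins, bundle.genes, bundle.elements):
        for row in df.itertuples():
            assert 0 <= row.start < row.end <= spec.chrom_lengths[row.chrom]


def test_elements_are_500bp_with_expected_classes():
    bundle = simulate_genome(small_spec())
    assert ((bundle.elements["end"] - bundle.elements["start"]) == 500).all()
    counts = bundle.elements["klass"].value_counts()
    assert counts["enhancer"] == 60 and counts["PRE"] == 20
    n_active = int((bundle.genes["active"] == 1).sum())
    assert counts["promoter"] == n_active


def test_chip_tracks_integer_nonnegative_and_depth_on_target(small_annotation, mock_model):
    chip, inp = simulate_chip_pair(small_annotation, mock_model, "mock", seed=21)
    for track, target in ((chip, mock_model.depth), (inp, mock_model.input_depth)):
        for arr in track.data.values():
            assert np.issubdtype(arr.dtype, np.integer)
            assert (arr >= 0).all()
        assert track.mean_depth() == pytest.approx(target, rel=0.05)


def test_chip_deterministic_for_fixed_seed(small_annotation, mock_model):
    a = simulate_chip(small_annotation, mock_model, "mock", seed=5)
    b = simulate_chip(small_annotation, mock_model, "mock", seed=5)
    for chrom in a.data:
        np.testing.assert_array_equal(a.data[chrom], b.data[chrom])
    c = simulate_chip(small_annotation, mock_model, "mock", seed=6)
    assert any(not np.array_equal(a.data[ch], c.data[ch]) for ch in a.data)


def test_inactive_genes_stay_at_baseline(small_annotation, mock_model):
    """With gating on, mean simulated ChIP depth over inactive genes matches
    the noise-free baseline expectation within 10%."""
    chip = simulate_chip(small_annotation, mock_model, "mock", seed=31)
    exp_chip, _ = expected_coverage(small_annotation, mock_model, "mock")
    inactive = small_annotation.genes[small_annotation.genes["active"] == 0]
    obs, exp = [], []
    for row in inactive.itertuples():
        obs.append(chip.data[row.chrom][row.start:row.end].mean())
        exp.append(exp_chip.data[row.chrom][row.start:row.end].mean())
    ratio = (np.mean(obs) / chip.mean_depth()) / (np.mean(exp) / exp_chip.mean_depth())
    assert ratio == pytest.approx(1.0, abs=0.1)


def test_zero_amplitude_gives_null_enrichment(small_annotation):
    model = FactorOccupancyModel(name="flat", amplitude=0.0, noise_dispersion=0.0)
    chip, inp = simulate_chip_pair(small_annotation, model, "mock", seed=13)
    track = compute_enrichment(chip, inp)
    pooled = np.concatenate(list(track.values.values()))
    assert abs(pooled.mean()) < 0.02
    # residual spread is pure counting noise at ~25 fragments per window
    assert pooled.std() < 0.45
    assert np.quantile(np.abs(pooled), 0.99) < 1.0


def test_invalid_model_parameters_rejected():
    with pytest.raises(ValueError, match="depth"):
        FactorOccupancyModel(name="x", depth=0.0)
    with pytest.raises(ValueError, match="mock"):
        FactorOccupancyModel(
            name="x", conditions={"mock": ConditionModifiers(decay_multiplier=2.0)}
        )
    model = FactorOccupancyModel(name="x")
    with pytest.raises(KeyError, match="unknown condition"):
        model.modifiers("iNope")


def test_planted_decay_scale_recovered():
    """Fitting exponential decay to noise-free enrichment returns the planted
    scale within 5% (gating off isolates the origin-distance term)."""
    spec = SyntheticGenomeSpec(
        chrom_lengths={"chr1": 1_700_000, "chr2": 1_700_000},
        origins={"chr1": [400_000, 1_200_000], "chr2": [400_000, 1_200_000]},
        seed=3,
    )
    ann = simulate_genome(spec)
    model = FactorOccupancyModel(name="R", gate_active_genes=False, decay_scale=25_000.0)
    chip, inp = expected_coverage(ann, model, "mock")
    track = compute_enrichment(chip, inp)
    fitted = fit_decay_scale(track, ann.origin_set())
    assert fitted == pytest.approx(25_000.0, rel=0.05)


def test_expression_effect_correlation_and_determinism():
    model = ExpressionEffectModel(n_genes=5000, effect_correlation=0.6)
    _, truth = simulate_expression(model, seed=17)
    r = np.corrcoef(truth["iPds5"], truth["iBrca2"])[0, 1]
    assert r == pytest.approx(0.6, abs=0.05)
    expr1, _ = simulate_expression(model, seed=17)
    expr2, _ = simulate_expression(model, seed=17)
    pd.testing.assert_frame_equal(expr1.values, expr2.values)


def test_expression_zero_effect_sd():
    model = ExpressionEffectModel(n_genes=200, effect_sd=0.0)
    _, truth = simulate_expression(model, seed=1)
    assert (truth.to_numpy() == 0.0).all()


def test_expression_replicate_minimum():
    with pytest.raises(ValueError, match="two replicates"):
        simulate_expression(ExpressionEffectModel(replicates_per_depletion=1), seed=1)


def test_expression_invalid_correlation():
    with pytest.raises(ValueError, match="correlation"):
        ExpressionEffectModel(effect_correlation=1.5)


def test_fiber_median_ratio_tracks_stall_factor():
    t1 = simulate_fibers(FiberModel(n_fibers=500, stall_factor=1.0), treated=True, seed=2)
    r1, _ = (t1.table["cldu_length_um"] / t1.table["idu_length_um"], None)
    assert np.median(r1) == pytest.approx(1.0, abs=0.05)
    t2 = simulate_fibers(FiberModel(n_fibers=500, stall_factor=0.5), treated=True, seed=2)
    r2 = t2.table["cldu_length_um"] / t2.table["idu_length_um"]
    assert np.median(r2) == pytest.approx(0.5, abs=0.05)
    # untreated fibers ignore the stall factor
    t3 = simulate_fibers(FiberModel(n_fibers=500, stall_factor=0.5), treated=False, seed=2)
    r3 = t3.table["cldu_length_um"] / t3.table["idu_length_um"]
    assert np.median(r3) == pytest.approx(1.0, abs=0.05)


def test_fiber_empty_table_and_positive_lengths():
    t = simulate_fibers(FiberModel(n_fibers=0), treated=False, seed=1)
    assert len(t) == 0
    t2 = simulate_fibers(FiberModel(n_fibers=300), treated=True, seed=4)
    assert (t2.table[["idu_length_um", "cldu_length_um"]] > 0).all().all()
    with pytest.raises(ValueError, match="stall"):
        FiberModel(stall_factor=0.0)
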