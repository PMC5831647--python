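"""Meta-origin binning, profiles, ratio profiles and per-bin Wilcoxon."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from metaorigin import (
    OriginBinMatrix,
    OriginSet,
    bin_matrix,
    bin_wilcoxon,
    mean_profile,
    ratio_profile,
)

from conftest import make_track, random_track


def oracle_bin_matrix(track, origins, flank=100_000, bin_size=10_000):
    """Direct per-bin recomputation over anchor midpoints."""
    n_bins = 2 * flank // bin_size
    mat = np.full((len(origins), n_bins), np.nan)
    for o, (chrom, center) in enumerate(zip(origins.chroms, origins.centers)):
        mids = track.anchor_midpoints(chrom)
        vals = track.values[chrom]
        for j in range(n_bins):
            lo = center - flank + j * bin_size
            hi = lo + bin_size
            if lo < 0 or hi > track.chrom_lengths[chrom]:
                continue
            sel = (mids >= lo) & (mids < hi)
            if sel.any():
                mat[o, j] = vals[sel].mean()
    return mat


def test_default_bin_count_and_constant_track():
    track = make_track({"c": np.full(5000, 1.25)})  # 250 kb of anchors
    origins = OriginSet(chroms=["c"], centers=[125_000])
    mat = bin_matrix(track, origins)
    assert mat.matrix.shape == (1, 20)
    finite = np.isfinite(mat.matrix[0])
    assert np.allclose(mat.matrix[0][finite], 1.25)


def test_bins_past_chromosome_end_are_missing():
    track = make_track({"c": np.zeros(1000)})  # ~50 kb of anchors
    origins = OriginSet(chroms=["c"], centers=[25_000])
    mat = bin_matrix(track, origins)
    row = mat.matrix[0]
    # bins reaching below 0 or beyond ~50 kb are NaN, central bins are not
    assert np.isnan(row[0]) and np.isnan(row[-1])
    assert np.isfinite(row[9]) and np.isfinite(row[10])


def test_unknown_chromosome_named_in_error(rng):
    track = random_track(rng, {"c": 100})
    origins = OriginSet(chroms=["nope"], centers=[1000])
    with pytest.raises(ValueError, match="nope"):
        bin_matrix(track, origins)


def test_bin_matrix_matches_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(3000, 6000))
        track = random_track(rng, {"c": n, "d": n // 2})
        origins = OriginSet(
            chroms=["c", "c", "d"],
            centers=[int(rng.integers(0, n * 50)) for _ in range(2)]
            + [int(rng.integers(0, n * 25))],
        )
        mat = bin_matrix(track, origins)
        want = oracle_bin_matrix(track, origins)
        np.testing.assert_allclose(mat.matrix, want, atol=1e-12, equal_nan=True)


def test_mean_profile_trivials_and_oracle(rng):
    track = random_track(rng, {"c": 5000})
    origins = OriginSet(chroms=["c"], centers=[120_000])
    mat = bin_matrix(track, origins)
    prof = mean_profile(mat)
    np.testing.assert_allclose(
        prof["mean_enrichment"].to_numpy(), mat.matrix[0], equal_nan=True
    )
    # rows r and 2 - r average to 1 everywhere
    twin = OriginBinMatrix(
        matrix=np.vstack([mat.matrix[0], 2.0 - mat.matrix[0]]),
        bin_offsets=mat.bin_offsets,
        origins=OriginSet(chroms=["c", "c"], centers=[120_000, 120_000]),
    )
    prof2 = mean_profile(twin)
    finite = np.isfinite(prof2["mean_enrichment"])
    assert np.allclose(prof2["mean_enrichment"][finite], 1.0)
    # random matrix column means
    m = rng.normal(size=(7, 20))
    mat3 = OriginBinMatrix(
        matrix=m.copy(), bin_offsets=mat.bin_offsets,
        origins=OriginSet(chroms=["c"] * 7, centers=[120_000] * 7),
    )
    np.testing.assert_allclose(
        mean_profile(mat3)["mean_enrichment"].to_numpy(), m.mean(axis=0), atol=1e-12
    )


def _matrix_pair(rng, n_origins=6, n_bins=20, offset=0.0):
    offsets = -100_000 + np.arange(n_bins) * 10_000
    origins = OriginSet(chroms=["c"] * n_origins, centers=[200_000] * n_origins)
    a = rng.normal(size=(n_origins, n_bins))
    b = a + offset
    return (
        OriginBinMatrix(matrix=a, bin_offsets=offsets, origins=origins),
        OriginBinMatrix(matrix=b, bin_offsets=offsets, origins=origins),
    )


def test_ratio_profile_identity_and_doubling(rng):
    num, _ = _matrix_pair(rng)
    same = ratio_profile(num, num)
    assert np.allclose(same.table["ratio"], 1.0)
    doubled = OriginBinMatrix(
        matrix=num.matrix + 1.0, bin_offsets=num.bin_offsets, origins=num.origins
    )
    # +1 in log2 is a factor 2 in the linear enrichment domain
    assert np.allclose(ratio_profile(doubled, num).table["ratio"], 2.0)


def test_ratio_profile_oracle_mean_of_ratios(rng):
    a, b = _matrix_pair(rng, offset=0.3)
    got = ratio_profile(a, b).table["ratio"].to_numpy()
    want = np.power(2.0, a.matrix - b.matrix).mean(axis=0)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_ratio_profile_shape_mismatch(rng):
    a, _ = _matrix_pair(rng, n_bins=20)
    b, _ = _matrix_pair(rng, n_bins=10)
    with pytest.raises(ValueError):
        ratio_profile(a, b)


def exact_signed_rank_p(diffs):
    """Enumerate all sign assignments of |diffs| for the two-sided p."""
    d = np.abs(np.asarray(diffs, dtype=float))
    ranks = pd.Series(d).rank().to_numpy()
    w_obs = ranks[np.asarray(diffs) > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    mean_w = ranks.sum() / 2
    more_extreme = np.sum(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return more_extreme / len(ws)


def test_bin_wilcoxon_five_positive_pairs():
    """n = 5 all-positive differences: exact two-sided p = 2/2^5 = 0.0625."""
    offsets = np.array([-10_000, 0])
    origins = OriginSet(chroms=["c"] * 5, centers=[200_000] * 5)
    mock = OriginBinMatrix(matrix=np.zeros((5, 2)), bin_offsets=offsets, origins=origins)
    diffs = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
    depleted = OriginBinMatrix(
        matrix=np.column_stack([diffs, diffs]), bin_offsets=offsets, origins=origins
    )
    res = bin_wilcoxon(mock, depleted)
    assert res.table["p"].to_numpy() == pytest.approx([0.0625, 0.0625])
    assert exact_signed_rank_p(diffs) == pytest.approx(0.0625)
    assert (res.table["direction"] == 1).all()


def test_bin_wilcoxon_matches_enumeration_oracle(rng):
    """Random small paired samples agree with full sign enumeration."""
    offsets = np.array([0])
    for _ in range(20):
        n = int(rng.integers(6, 11))
        origins = OriginSet(chroms=["c"] * n, centers=[200_000] * n)
        d = rng.normal(0.3, 1.0, n)
        mock = OriginBinMatrix(np.zeros((n, 1)), offsets, origins)
        depl = OriginBinMatrix(d[:, None], offsets, origins)
        p = bin_wilcoxon(mock, depl).table["p"].iloc[0]
        assert p == pytest.approx(exact_signed_rank_p(d), abs=1e-12)


def test_bin_wilcoxon_degenerate_equal_matrices(rng):
    """Identical matrices leave no usable pairs: missing p."""
    mock, _ = _matrix_pair(rng)
    res = bin_wilcoxon(mock, mock)
    assert res.table["p"].isna().all()


def test_origin_set_io(tmp_path):
    bed = tmp_path / "ori.bed"
    bed.write_text("chr1\t100\t200\tori_1\t0\t.\nchr2\t5000\t5100\tori_2\t0\t.\n")
    origins = OriginSet.from_bed(bed)
    assert origins.chroms == ["chr1", "chr2"]
    assert origins.centers == [150, 5050]
    two_col = tmp_path / "ori.tsv"
    two_col.write_text("chr1\t150\nchr2\t5050\n")
    origins2 = OriginSet.from_bed(two_col)
    assert origins2.centers == origins.centers


def test_symmetric_model_gives_symmetric_profile(small_annotation, mock_model):
    """An occupancy model symmetric about the origin yields a mean profile
    symmetric about the center within Monte-Carlo error."""
    from metaorigin import compute_enrichment, simulate_chip, simulate_input

    chip = simulate_chip(small_annotation, mock_model, "mock", seed=42)
    inp = simulate_input(small_annotation, mock_model, seed=42)
    track = compute_enrichment(chip, inp)
    prof = mean_profile(bin_matrix(track, small_annotation.origin_set()))
    vals = prof["mean_enrichment"].to_numpy()
    left, right = vals[:10], vals[::-1][:10]
    # with 8 origins the per-bin Monte-Carlo error is sizeable; require the
    # two half-profiles to track each other and not diverge grossly
    assert np.corrcoef(left, right)[0, 1] > 0.8
    assert np.nanmax(np.abs(left - right)) < 0.6
    # occupancy is maximal at the center and decays outward
    assert np.nanargmax(vals) in (9, 10)
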