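"""Percentile-threshold region calling and overlap statistics."""

import subprocess

import numpy as np
import pytest

from metaorigin import BindingRegion, OverlapReport, call_regions, intersect_region_sets
from metaorigin.regions import read_regions_bed, write_regions_bed

from conftest import make_track, random_track


def oracle_call(track, percentile=95.0, min_len=300, chromosomes=None):
    """Brute-force oracle: test every anchor, merge runs, extend, merge, filter."""
    chroms = sorted(track.values) if chromosomes is None else list(chromosomes)
    pooled = np.concatenate([track.values[c] for c in chroms])
    threshold = np.percentile(pooled, percentile)
    out = []
    for chrom in chroms:
        vals = track.values[chrom]
        runs = []
        current = None
        for i, v in enumerate(vals):
            if v >= threshold:
                if current is None:
                    current = [i, i]
                else:
                    current[1] = i
            else:
                if current is not None:
                    runs.append(current)
                    current = None
        if current is not None:
            runs.append(current)
        intervals = [[i0 * track.step, i1 * track.step + track.window] for i0, i1 in runs]
        merged = []
        for s, e in intervals:
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_len:
                anchor_vals = [
                    v for i, v in enumerate(vals)
                    if i * track.step >= s and i * track.step + track.window <= e and v >= threshold
                ]
                out.append(BindingRegion(chrom, s, e, float(np.mean(anchor_vals))))
    return out


def test_constant_track_degenerate_all_ties():
    """A constant track puts every anchor at the threshold: one region per
    chromosome (the documented all-ties degenerate case)."""
    track = make_track({"c": np.zeros(30), "d": np.zeros(20)})
    regions = call_regions(track)
    assert len(regions) == 2
    by_chrom = {r.chrom: r for r in regions}
    assert by_chrom["c"].start == 0 and by_chrom["c"].end == 29 * 50 + 250
    assert by_chrom["d"].start == 0 and by_chrom["d"].end == 19 * 50 + 250


def test_min_length_filter():
    """A single above-threshold anchor spans only 250 bp and is dropped; a
    two-anchor run spans 300 bp and is kept."""
    vals = np.zeros(100)
    vals[50] = 10.0
    track = make_track({"c": vals})
    assert call_regions(track, percentile=99) == []
    vals2 = np.zeros(100)
    vals2[50:52] = 10.0
    track2 = make_track({"c": vals2})
    regions = call_regions(track2, percentile=99)
    assert len(regions) == 1
    assert regions[0].length == 300


def test_empty_include_list_rejected(rng):
    track = random_track(rng, {"c": 50})
    with pytest.raises(ValueError, match="include-list"):
        call_regions(track, chromosomes=[])


def test_call_regions_matches_oracle(rng):
    """200 random tracks produce region sets identical to the brute-force
    oracle."""
    for i in range(200):
        n = int(rng.integers(20, 150))
        track = make_track({"c": rng.normal(0, 1, n), "d": rng.normal(0, 1, max(5, n // 2))})
        pct = float(rng.choice([50, 80, 90, 95]))
        got = call_regions(track, percentile=pct)
        want = oracle_call(track, percentile=pct)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert (g.chrom, g.start, g.end) == (w.chrom, w.start, w.end)
            assert g.mean_enrichment == pytest.approx(w.mean_enrichment)


def test_regions_disjoint_and_percentile_monotone(rng):
    """Called regions never overlap, and raising the percentile never
    increases the total called basepairs."""
    for _ in range(20):
        track = make_track({"c": rng.normal(0, 1, 300)})
        prev_bp = None
        for pct in (50, 70, 90, 95, 99):
            regions = call_regions(track, percentile=pct)
            for a, b in zip(regions, regions[1:]):
                assert a.end <= b.start
            total = sum(r.length for r in regions)
            if prev_bp is not None:
                assert total <= prev_bp
            prev_bp = total


def test_overlap_worked_example():
    """6,452 regions with 3,600 overlapping reports a 56% overlap fraction."""
    rep = OverlapReport.from_counts(n_a=6452, n_b=6430, n_overlap=3600)
    assert rep.fraction_pct == 56


def test_overlap_self_and_disjoint():
    a = [BindingRegion("c", 0, 500, 1.0), BindingRegion("c", 1000, 1500, 1.0)]
    rep = intersect_region_sets(a, a)
    assert rep.n_overlap == 2 and rep.fraction_pct == 100
    b = [BindingRegion("d", 0, 500, 1.0)]
    assert intersect_region_sets(a, b).n_overlap == 0


def test_overlap_halfopen_semantics():
    """Regions that only touch end-to-start share no base and do not count."""
    a = [BindingRegion("c", 0, 500, 1.0)]
    b = [BindingRegion("c", 500, 900, 1.0)]
    assert intersect_region_sets(a, b).n_overlap == 0
    c = [BindingRegion("c", 499, 900, 1.0)]
    assert intersect_region_sets(a, c).n_overlap == 1


def test_unsorted_input_rejected():
    bad = [BindingRegion("c", 1000, 1500, 1.0), BindingRegion("c", 0, 500, 1.0)]
    good = [BindingRegion("c", 0, 400, 1.0)]
    with pytest.raises(ValueError, match="unsorted"):
        intersect_region_sets(bad, good)


def random_region_set(rng, n, chrom="c"):
    starts = np.sort(rng.choice(np.arange(0, 20000, 10), size=n, replace=False))
    regions = []
    prev_end = -1
    for s in starts:
        s = max(int(s), prev_end + 1)
        e = s + int(rng.integers(10, 400))
        regions.append(BindingRegion(chrom, s, e, 0.0))
        prev_end = e
    return regions


def test_overlap_matches_bruteforce_and_bedtools(rng, tmp_path):
    """Overlap counts agree with a double-loop oracle and with bedtools."""
    for trial in range(20):
        a = random_region_set(rng, int(rng.integers(3, 30)))
        b = random_region_set(rng, int(rng.integers(3, 30)))
        rep = intersect_region_sets(a, b)
        brute = sum(
            1 for r in a if any(r.start < s.end and s.start < r.end for s in b)
        )
        assert rep.n_overlap == brute

    a = random_region_set(rng, 25)
    b = random_region_set(rng, 25)
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    write_regions_bed(a, fa)
    write_regions_bed(b, fb)
    res = subprocess.run(
        ["bedtools", "intersect", "-u", "-a", str(fa), "-b", str(fb)],
        capture_output=True, text=True, check=True,
    )
    n_bedtools = len([line for line in res.stdout.splitlines() if line.strip()])
    assert intersect_region_sets(a, b).n_overlap == n_bedtools


def test_regions_bed_roundtrip(tmp_path, rng):
    regions = random_region_set(rng, 10)
    path = tmp_path / "r.bed"
    write_regions_bed(regions, path)
    back = read_regions_bed(path)
    assert [(r.chrom, r.start, r.end) for r in back] == [
        (r.chrom, r.start, r.end) for r in regions
    ]
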