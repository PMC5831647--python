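"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes so that
every stage runs on data with known ground truth:

* a genome with replication origins, active/inactive genes and 500 bp
  regulatory elements (promoters at active gene starts, extragenic enhancers,
  PREs);
* ChIP/input coverage-track pairs in which factor occupancy is maximal at
  origin centers and decays exponentially with distance to the nearest
  origin, is gated to active genes (occupancy elsewhere stays at baseline,
  emulating the skipping of inactive genes and intergenic DNA), and responds
  to depletion conditions through multipliers on the decay scale, the
  origin-center amplitude and the flank amplitude;
* expression matrices whose per-depletion true log2 fold-change vectors share
  a latent effect (target pairwise correlation ~0.6 between paired factors)
  plus replicate noise tuned so replicate correlations exceed 0.95;
* log-normal DNA fiber tract tables in which fork stalling shrinks the
  second-label (CldU) tract by a multiplicative stall factor.

All randomness flows from one explicit seed per call; fixed seed means
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elements import ELEMENT_LENGTH, ElementSet
from .enrichment import compute_enrichment, replicate_correlation
from .origins import OriginSet
from .tracks import CoverageTrack

__all__ = [
    "SyntheticGenomeSpec",
    "AnnotationBundle",
    "FactorOccupancyModel",
    "ConditionModifiers",
    "ExpressionEffectModel",
    "FiberModel",
    "simulate_genome",
    "simulate_chip_pair",
    "simulate_chip",
    "simulate_input",
    "expected_coverage",
    "calibrate_dispersion",
    "simulate_expression",
    "simulate_fibers",
    "fit_decay_scale",
    "full_scale_genome_spec",
]

FRAGMENT_LENGTH = 300  # fixed sonication-size fragment extension, bp
EDGE_MARGIN = 200_000  # origins stay this far from chromosome ends


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome and its annotations.

    Origins are placed explicitly (positions per chromosome); genes tile the
    chromosomes with a given active fraction; promoters sit at active gene
    starts, enhancers and PREs are placed in intergenic space.  All elements
    are exactly 500 bp.
    """

    chrom_lengths: dict[str, int]
    origins: dict[str, list[int]]
    seed: int = 0
    gene_length: int = 5_000
    gene_spacing: int = 2_500
    active_fraction: float = 0.55
    #: activity probability within +/-100 kb of an origin; origins lie in
    #: active-gene-rich regions, so genes there are active more often
    origin_active_fraction: float = 0.8
    gene_strength_log_sd: float = 0.6  # per-gene occupancy multiplier spread
    n_enhancers: int = 60
    n_pres: int = 20
    allow_edge_origins: bool = False

    def validate(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length < 1000:
                raise ValueError(f"{chrom!r}: chromosome must be >= 1 kb")
        for chrom, positions in self.origins.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"origins on unknown chromosome {chrom!r}")
            length = self.chrom_lengths[chrom]
            for p in positions:
                if not 0 <= p < length:
                    raise ValueError(f"origin {chrom}:{p} outside chromosome bounds")
                if not self.allow_edge_origins and not (
                    EDGE_MARGIN <= p <= length - EDGE_MARGIN
                ):
                    raise ValueError(
                        f"origin {chrom}:{p} closer than {EDGE_MARGIN} bp to a "
                        "chromosome end (set allow_edge_origins to permit)"
                    )


@dataclass
class AnnotationBundle:
    """Origins, genes (with activity) and elements (with class) as frames."""

    chrom_lengths: dict[str, int]
    origins: pd.DataFrame   # chrom, start, end, name
    genes: pd.DataFrame     # chrom, start, end, name, active (0/1)
    elements: pd.DataFrame  # chrom, start, end, klass

    def origin_set(self, label: str = "origins") -> OriginSet:
        centers = ((self.origins["start"] + self.origins["end"]) // 2).astype(int)
        return OriginSet(chroms=list(self.origins["chrom"]), centers=list(centers), label=label)

    def element_set(self) -> ElementSet:
        return ElementSet(table=self.elements.copy())

    def active_gene_mask(self) -> dict[str, np.ndarray]:
        """Boolean per-base mask of active-gene bases per chromosome."""
        masks = {c: np.zeros(length, dtype=bool) for c, length in self.chrom_lengths.items()}
        active = self.genes[self.genes["active"] == 1]
        for chrom, start, end in zip(active["chrom"], active["start"], active["end"]):
            masks[chrom][start:end] = True
        return masks

    def gene_strength_mask(self) -> dict[str, np.ndarray]:
        """Per-base occupancy multiplier: gene strength inside active genes,
        zero elsewhere (strength defaults to 1 when the column is absent)."""
        masks = {c: np.zeros(length, dtype=np.float32) for c, length in self.chrom_lengths.items()}
        active = self.genes[self.genes["active"] == 1]
        strengths = (
            active["strength"] if "strength" in active.columns
            else pd.Series(1.0, index=active.index)
        )
        for chrom, start, end, s in zip(
            active["chrom"], active["start"], active["end"], strengths
        ):
            masks[chrom][start:end] = s
        return masks

    def write_bed(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        ori = self.origins.copy()
        ori["score"] = 0
        ori["strand"] = "."
        ori.to_csv(outdir / "origins.bed", sep="\t", header=False, index=False)
        genes = self.genes[["chrom", "start", "end", "name", "active"]].copy()
        genes["strand"] = "."
        genes.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
        el = self.elements.copy()
        el["score"] = 0
        el["strand"] = "."
        el.to_csv(outdir / "elements.bed", sep="\t", header=False, index=False)


def simulate_genome(spec: SyntheticGenomeSpec) -> AnnotationBundle:
    """Generate the annotation bundle for a synthetic genome spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ori_rows = []
    i = 0
    for chrom in sorted(spec.origins):
        for pos in spec.origins[chrom]:
            i += 1
            ori_rows.append((chrom, int(pos), int(pos) + 1, f"ori_{i}"))
    origins = pd.DataFrame(ori_rows, columns=["chrom", "start", "end", "name"])

    gene_rows = []
    g = 0
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        centers = np.sort(np.array(spec.origins.get(chrom, []), dtype=np.int64))
        pos = int(rng.integers(0, spec.gene_spacing + 1))
        while pos + spec.gene_length <= length:
            g += 1
            mid = pos + spec.gene_length // 2
            near_origin = bool(len(centers)) and bool(
                np.min(np.abs(centers - mid)) <= 100_000
            )
            p_active = spec.origin_active_fraction if near_origin else spec.active_fraction
            active = int(rng.random() < p_active)
            # per-gene occupancy multiplier: genes differ in how much factor
            # they bind, and that structure is shared across replicates and
            # conditions (it is biology, not sampling noise)
            strength = float(np.exp(spec.gene_strength_log_sd * rng.normal()))
            gene_rows.append((chrom, pos, pos + spec.gene_length, f"gene_{g}", active, strength))
            pos += spec.gene_length + spec.gene_spacing
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "name", "active", "strength"]
    )

    el_rows = []
    # promoters: one 500 bp element at the start of each active gene
    for row in genes[genes["active"] == 1].itertuples():
        el_rows.append((row.chrom, row.start, row.start + ELEMENT_LENGTH, "promoter"))
    # enhancers and PREs: placed in the gaps between genes
    gaps = []
    for chrom in sorted(spec.chrom_lengths):
        sub = genes[genes["chrom"] == chrom]
        prev = 0
        for row in sub.itertuples():
            if row.start - prev >= ELEMENT_LENGTH:
                gaps.append((chrom, prev, row.start))
            prev = row.end
        if spec.chrom_lengths[chrom] - prev >= ELEMENT_LENGTH:
            gaps.append((chrom, prev, spec.chrom_lengths[chrom]))
    for klass, count in (("enhancer", spec.n_enhancers), ("PRE", spec.n_pres)):
        for _ in range(count):
            if not gaps:
                raise ValueError("no intergenic space left for elements")
            chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
            start = int(rng.integers(lo, hi - ELEMENT_LENGTH + 1))
            el_rows.append((chrom, start, start + ELEMENT_LENGTH, klass))
    elements = pd.DataFrame(el_rows, columns=["chrom", "start", "end", "klass"])
    elements = elements.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    bundle = AnnotationBundle(
        chrom_lengths=dict(spec.chrom_lengths),
        origins=origins,
        genes=genes,
        elements=elements,
    )
    # brute-force bounds check on everything we emit
    for df, what in ((origins, "origin"), (genes, "gene"), (elements, "element")):
        for row in df.itertuples():
            if row.start < 0 or row.end > spec.chrom_lengths[row.chrom]:
                raise ValueError(f"{what} outside chromosome bounds: {row}")
    return bundle


# ---------------------------------------------------------------------------
# ChIP occupancy model and read simulation
# ---------------------------------------------------------------------------

@dataclass
class ConditionModifiers:
    """Depletion-condition multipliers applied to the occupancy model."""

    decay_multiplier: float = 1.0
    origin_multiplier: float = 1.0
    flank_multiplier: float = 1.0

    def is_mock(self) -> bool:
        return (
            self.decay_multiplier == 1.0
            and self.origin_multiplier == 1.0
            and self.flank_multiplier == 1.0
        )


#: canonical depletion conditions emulating the study's qualitative effects:
#: Pds5/Wapl loss extends cohesin domains (longer decay, higher flanks);
#: Brca2 loss raises SA at origins; Pds5 loss lowers SA at origins.
STANDARD_CONDITIONS: dict[str, ConditionModifiers] = {
    "mock": ConditionModifiers(),
    "iPds5_domain": ConditionModifiers(decay_multiplier=2.0, flank_multiplier=1.5),
    "iWapl_domain": ConditionModifiers(decay_multiplier=2.0, flank_multiplier=1.5),
    "iBrca2_SA": ConditionModifiers(origin_multiplier=1.6),
    "iPds5_SA": ConditionModifiers(origin_multiplier=0.5, decay_multiplier=2.0,
                                   flank_multiplier=1.5),
}


@dataclass
class FactorOccupancyModel:
    """Origin-centered occupancy model for one ChIP factor.

    Expected occupancy at position x is

        baseline + amplitude * m(d) * exp(-d / (decay_scale * decay_mult))

    where d is the distance to the nearest origin and
    ``m(d) = flank_mult + (origin_mult - flank_mult) * exp(-d / core_scale)``
    interpolates smoothly between the origin-center and flank multipliers.
    With active-gene gating on, occupancy outside active genes is baseline
    only.  ``element_amplitudes`` optionally adds class-specific occupancy
    within regulatory elements for planted per-class effects.
    """

    name: str
    baseline: float = 1.0
    amplitude: float = 6.0
    decay_scale: float = 25_000.0
    core_scale: float = 5_000.0
    #: intrinsic origin-center occupancy multiplier of the factor itself
    #: (e.g. SA accumulates at origin cores above its flank stoichiometry);
    #: depletion-condition origin multipliers act on top of this
    origin_boost: float = 1.0
    gate_active_genes: bool = True
    conditions: dict[str, ConditionModifiers] = field(
        default_factory=lambda: {"mock": ConditionModifiers()}
    )
    noise_dispersion: float = 0.02
    depth: float = 30.0
    input_depth: float = 45.0
    element_amplitudes: dict[str, float] = field(default_factory=dict)
    noise_block: int = 500  # bp; gamma noise is shared within a block

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.input_depth <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.amplitude < 0 or self.baseline <= 0:
            raise ValueError("baseline must be positive and amplitude non-negative")
        if self.decay_scale <= 0 or self.core_scale <= 0:
            raise ValueError("decay scales must be positive")
        mock = self.conditions.get("mock")
        if mock is not None and not mock.is_mock():
            raise ValueError("mock condition must have all multipliers = 1")

    def modifiers(self, condition: str) -> ConditionModifiers:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return self.conditions[condition]


def _distance_to_nearest_origin(length: int, positions: np.ndarray) -> np.ndarray:
    """Per-base distance to the nearest origin, built from linear ramps."""
    if len(positions) == 0:
        return np.full(length, np.inf, dtype=np.float32)
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    bounds = np.concatenate([[0], (pos[:-1] + pos[1:]) // 2 + 1, [length]])
    out = np.empty(length, dtype=np.float32)
    for p, lo, hi in zip(pos, bounds[:-1], bounds[1:]):
        out[lo:hi] = np.abs(np.arange(lo, hi, dtype=np.float32) - np.float32(p))
    return out


def _occupancy(
    annotation: AnnotationBundle,
    model: FactorOccupancyModel,
    condition: str,
) -> dict[str, np.ndarray]:
    mods = model.modifiers(condition)
    origin_by_chrom: dict[str, list[int]] = {}
    for row in annotation.origins.itertuples():
        origin_by_chrom.setdefault(row.chrom, []).append((row.start + row.end) // 2)
    masks = annotation.gene_strength_mask() if model.gate_active_genes else None

    occ = {}
    for chrom, length in annotation.chrom_lengths.items():
        centers = origin_by_chrom.get(chrom, [])
        if not centers:
            # origin-free chromosome: occupancy is flat baseline
            arr = np.full(length, np.float32(model.baseline), dtype=np.float32)
            signal = None
        else:
            d = _distance_to_nearest_origin(length, np.array(centers))
            origin_mult = mods.origin_multiplier * model.origin_boost
            with np.errstate(over="ignore", under="ignore"):
                core_w = np.exp(-d / np.float32(model.core_scale))
                mult = np.float32(mods.flank_multiplier) + np.float32(
                    origin_mult - mods.flank_multiplier
                ) * core_w
                decay = np.exp(-d / np.float32(model.decay_scale * mods.decay_multiplier))
            signal = np.float32(model.amplitude) * mult * decay
            if masks is not None:
                signal = signal * masks[chrom]
            arr = np.float32(model.baseline) + signal
        if model.element_amplitudes:
            sub = annotation.elements[annotation.elements["chrom"] == chrom]
            for row in sub.itertuples():
                boost = model.element_amplitudes.get(row.klass, 0.0)
                if boost:
                    arr[row.start:row.end] += boost
        occ[chrom] = arr
    return occ


def _reads_from_rates(
    rates: dict[str, np.ndarray],
    total_depth: float,
    dispersion: float,
    block: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Poisson(-gamma) fragment starts extended to per-base coverage."""
    genome_len = sum(len(r) for r in rates.values())
    n_target = total_depth * genome_len / FRAGMENT_LENGTH
    total_rate = sum(float(r[: len(r) - FRAGMENT_LENGTH + 1].sum()) for r in rates.values())
    data = {}
    for chrom, r in rates.items():
        n = len(r)
        ls = n - FRAGMENT_LENGTH + 1
        if ls <= 0:
            data[chrom] = np.zeros(n, dtype=np.int32)
            continue
        scale = n_target / total_rate
        flat = r.min() == r.max()  # uniform rates: scalar fast path
        if dispersion > 0:
            n_blocks = (ls + block - 1) // block
            g = rng.gamma(shape=1.0 / dispersion, scale=dispersion, size=n_blocks)
            lam = np.multiply(r[:ls], scale, dtype=np.float64)
            lam *= np.repeat(g, block)[:ls]
            starts = rng.poisson(lam)
        elif flat:
            starts = rng.poisson(float(r[0]) * scale, size=ls)
        else:
            starts = rng.poisson(np.multiply(r[:ls], scale, dtype=np.float64))
        cs = np.cumsum(starts, dtype=np.int32)
        # coverage[i] = number of fragments whose [start, start+300) covers i
        full = np.empty(n, dtype=np.int32)
        full[:ls] = cs
        full[ls:] = cs[-1]
        cov = np.empty(n, dtype=np.int32)
        cov[:FRAGMENT_LENGTH] = full[:FRAGMENT_LENGTH]
        np.subtract(full[FRAGMENT_LENGTH:], full[:-FRAGMENT_LENGTH], out=cov[FRAGMENT_LENGTH:])
        data[chrom] = cov
    return data


def simulate_chip_pair(
    annotation: AnnotationBundle,
    model: FactorOccupancyModel,
    condition: str = "mock",
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate one (ChIP, input) coverage-track pair.

    The ChIP track draws fragment starts at rates proportional to the
    condition-modified occupancy; the input track is occupancy-independent
    Poisson noise around a uniform expected depth.  Counts are non-negative
    integers and the total base coverage is within a few percent of the
    requested depths.
    """
    return (
        simulate_chip(annotation, model, condition, seed),
        simulate_input(annotation, model, seed=seed, condition=condition),
    )


def simulate_chip(
    annotation: AnnotationBundle,
    model: FactorOccupancyModel,
    condition: str = "mock",
    seed: int = 0,
) -> CoverageTrack:
    """Simulate the ChIP track alone (see :func:`simulate_chip_pair`)."""
    import zlib

    ss = np.random.SeedSequence(entropy=(seed, zlib.crc32(condition.encode()), 7))
    rng_chip = np.random.default_rng(ss.spawn(2)[0])
    occ = _occupancy(annotation, model, condition)
    chip = _reads_from_rates(occ, model.depth, model.noise_dispersion, model.noise_block, rng_chip)
    return CoverageTrack(data=chip, sample=f"{model.name}_{condition}")


def simulate_input(
    annotation: AnnotationBundle,
    model: FactorOccupancyModel,
    seed: int = 0,
    condition: str = "mock",
) -> CoverageTrack:
    """Simulate a deep input track (uniform expected depth, Poisson noise).

    One input may be shared as the normalization reference for several ChIP
    conditions, mirroring how multiple precipitations are normalized to the
    same deeply sequenced input chromatin.
    """
    import zlib

    ss = np.random.SeedSequence(entropy=(seed, zlib.crc32(condition.encode()), 7))
    rng_input = np.random.default_rng(ss.spawn(2)[1])
    flat = {
        c: np.ones(length, dtype=np.float32)
        for c, length in annotation.chrom_lengths.items()
    }
    inp = _reads_from_rates(flat, model.input_depth, 0.0, model.noise_block, rng_input)
    return CoverageTrack(data=inp, sample=f"input_{condition}")


def expected_coverage(
    annotation: AnnotationBundle,
    model: FactorOccupancyModel,
    condition: str = "mock",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Noise-free expected (ChIP, input) coverage, for planted-model checks.

    Expected fragment-start rates are extended by the fragment length exactly
    as in the stochastic simulator, but no sampling noise is added (values
    are rounded expected counts at a high nominal depth).
    """
    occ = _occupancy(annotation, model, condition)
    genome_len = sum(annotation.chrom_lengths.values())

    def extend(rates: dict[str, np.ndarray], depth: float) -> dict[str, np.ndarray]:
        n_target = depth * genome_len / FRAGMENT_LENGTH
        total = sum(float(r[: len(r) - FRAGMENT_LENGTH + 1].sum()) for r in rates.values())
        out = {}
        for chrom, r in rates.items():
            ls = len(r) - FRAGMENT_LENGTH + 1
            lam = r[:ls] * (n_target / total)
            cs = np.cumsum(lam)
            full = np.concatenate([cs, np.full(len(r) - ls, cs[-1])])
            shifted = np.concatenate([np.zeros(FRAGMENT_LENGTH), full[:-FRAGMENT_LENGTH]])
            out[chrom] = np.round((full - shifted) * 1000).astype(np.int64)
        return out

    chip = extend(occ, model.depth)
    flat = {c: np.ones(length) for c, length in annotation.chrom_lengths.items()}
    inp = extend(flat, model.input_depth)
    return (
        CoverageTrack(data=chip, sample=f"{model.name}_{condition}_expected"),
        CoverageTrack(data=inp, sample="input_expected"),
    )


def calibrate_dispersion(
    annotation: AnnotationBundle,
    model: FactorOccupancyModel,
    target_band: tuple[float, float] = (0.65, 0.9),
    condition: str = "mock",
    seed: int = 0,
    max_iter: int = 12,
) -> float:
    """Search the noise dispersion so replicate enrichment correlation lands
    in the requested band.

    Replicate correlation decreases monotonically with dispersion; a
    bisection on log-dispersion targets the band midpoint.  Returns the
    calibrated dispersion (the model is not mutated).
    """
    lo, hi = 1e-4, 20.0
    target = 0.5 * (target_band[0] + target_band[1])

    def corr_at(disp: float, it: int) -> float:
        m = replace(model, noise_dispersion=disp)
        c1, i1 = simulate_chip_pair(annotation, m, condition, seed=seed * 1000 + 2 * it)
        c2, i2 = simulate_chip_pair(annotation, m, condition, seed=seed * 1000 + 2 * it + 1)
        e1 = compute_enrichment(c1, i1)
        e2 = compute_enrichment(c2, i2)
        return replicate_correlation(e1, e2)

    if corr_at(lo, 0) < target:
        return lo
    if corr_at(hi, 1) > target:
        return hi
    for it in range(2, max_iter + 2):
        mid = float(np.sqrt(lo * hi))
        if corr_at(mid, it) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def fit_decay_scale(track, origins: OriginSet, max_distance: float = 100_000.0) -> float:
    """Recover the planted decay scale from an enrichment track.

    Fits ``a * exp(-d/s) + c`` to linear-domain enrichment versus distance to
    the nearest origin (anchor midpoints, distances binned every 1 kb).
    Intended for noise-free expected tracks with gating off.
    """
    from scipy.optimize import curve_fit

    dists, vals = [], []
    centers_by_chrom: dict[str, list[int]] = {}
    for chrom, center in zip(origins.chroms, origins.centers):
        centers_by_chrom.setdefault(chrom, []).append(center)
    for chrom in track.values:
        mids = track.anchor_midpoints(chrom)
        pos = np.array(centers_by_chrom.get(chrom, []))
        if len(pos) == 0:
            continue
        idx = np.searchsorted(np.sort(pos), mids)
        pos_sorted = np.sort(pos)
        left = pos_sorted[np.clip(idx - 1, 0, len(pos) - 1)]
        right = pos_sorted[np.clip(idx, 0, len(pos) - 1)]
        d = np.minimum(np.abs(mids - left), np.abs(mids - right))
        keep = d <= max_distance
        dists.append(d[keep])
        vals.append(np.power(2.0, track.values[chrom][keep]))
    d = np.concatenate(dists)
    v = np.concatenate(vals)
    order = np.argsort(d)
    d, v = d[order], v[order]
    edges = np.arange(0, max_distance + 1000, 1000)
    which = np.digitize(d, edges) - 1
    prof = np.array([v[which == i].mean() for i in range(len(edges) - 1) if (which == i).any()])
    dd = np.array([edges[i] + 500 for i in range(len(edges) - 1) if (which == i).any()])

    def f(x, a, s, c):
        return a * np.exp(-x / s) + c

    popt, _ = curve_fit(f, dd, prof, p0=(prof[0] - prof[-1], 20_000.0, prof[-1]),
                        maxfev=20_000)
    return float(popt[1])


def full_scale_genome_spec(seed: int = 0, spacing: int = 160_000,
                           background_mult: float = 3.0) -> SyntheticGenomeSpec:
    """Genome spec at the study's full origin count: 78 early origins.

    Origins sit on two arms with the given spacing; origin-free chromosomes
    supply ``background_mult`` times the origin-territory mass so that
    library-depth renormalization is not dominated by the origin territory
    (in the fly genome the strongest early origins cover a small fraction of
    the euchromatin).
    """
    chroms: dict[str, int] = {}
    origins: dict[str, list[int]] = {}
    for c in ("chr2L", "chr2R"):
        pos = [EDGE_MARGIN + i * spacing for i in range(39)]
        origins[c] = pos
        chroms[c] = pos[-1] + EDGE_MARGIN
    territory = sum(chroms.values())
    for c in ("chr3L", "chr3R", "chrX"):
        chroms[c] = int(territory * background_mult / 3)
        origins[c] = []
    return SyntheticGenomeSpec(chrom_lengths=chroms, origins=origins, seed=seed)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionEffectModel:
    """Latent-effect model for depletion expression contrasts.

    Each depletion's true per-gene log2 fold-change is
    ``sd * mask * (sqrt(rho) * z_shared + sqrt(1-rho) * z_depl)`` with a
    shared affected-gene mask, giving an exact target pairwise correlation
    ``rho`` between depletion effect vectors.
    """

    n_genes: int = 5000
    depletions: tuple[str, ...] = ("iPds5", "iBrca2")
    effect_correlation: float = 0.6
    effect_sd: float = 0.5
    affected_fraction: float = 0.3
    replicate_noise_sd: float = 0.15  # log2 units
    replicates_per_depletion: int = 3
    mock_replicates: int = 6
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.effect_correlation <= 1.0:
            raise ValueError("target correlation must be in [-1, 1]")
        if self.replicates_per_depletion < 0 or self.mock_replicates < 0:
            raise ValueError("replicate counts must be non-negative")


def simulate_expression(model: ExpressionEffectModel, seed: int = 0):
    """Simulate an expression matrix plus the true log2 fold-change vectors.

    Returns ``(ExpressionMatrix, truth)`` where truth is a genes x depletions
    frame of planted log2 fold-changes.  Raises if fewer than two replicates
    per condition are requested (the contrast would be untestable).
    """
    from .expression import ExpressionMatrix

    if model.replicates_per_depletion < 2 or model.mock_replicates < 2:
        raise ValueError("need at least two replicates per condition")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i+1}" for i in range(model.n_genes)]
    baseline = rng.normal(model.baseline_log2_mean, model.baseline_log2_sd, model.n_genes)
    mask = rng.random(model.n_genes) < model.affected_fraction
    z_shared = rng.normal(size=model.n_genes)
    rho = model.effect_correlation
    truth = {}
    for dep in model.depletions:
        z = rng.normal(size=model.n_genes)
        eff = model.effect_sd * mask * (
            np.sqrt(abs(rho)) * np.sign(rho) * z_shared + np.sqrt(1 - abs(rho)) * z
        )
        truth[dep] = eff
    truth = pd.DataFrame(truth, index=genes)

    cols, data, cond = [], [], {}
    for r in range(model.mock_replicates):
        name = f"mock_r{r+1}"
        cols.append(name)
        cond[name] = "mock"
        data.append(baseline + rng.normal(0, model.replicate_noise_sd, model.n_genes))
    for dep in model.depletions:
        for r in range(model.replicates_per_depletion):
            name = f"{dep}_r{r+1}"
            cols.append(name)
            cond[name] = dep
            data.append(
                baseline + truth[dep].to_numpy()
                + rng.normal(0, model.replicate_noise_sd, model.n_genes)
            )
    values = pd.DataFrame(np.power(2.0, np.column_stack(data)), index=genes, columns=cols)
    return ExpressionMatrix(values=values, conditions=pd.Series(cond)), truth


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------

@dataclass
class FiberModel:
    """Log-normal dual-label fiber tract model.

    First-label (IdU) tract lengths are log-normal with the given median and
    log-scale SD; the connected second-label (CldU) tract is the first tract
    times the stall factor (applied under treatment) times log-normal ratio
    noise, so the median second/first ratio equals the stall factor.
    """

    median_um: float = 8.0
    log_sd: float = 0.4
    stall_factor: float = 0.5
    ratio_log_sd: float = 0.25
    n_fibers: int = 500
    group: str = "Mock"

    def __post_init__(self) -> None:
        if self.median_um <= 0:
            raise ValueError("median tract length must be positive")
        if not 0 < self.stall_factor <= 1:
            raise ValueError("stall factor must be in (0, 1]")


def simulate_fibers(model: FiberModel, treated: bool = False, seed: int = 0):
    """Simulate a connected-tract fiber table (lengths strictly positive)."""
    from .fibers import FiberTable

    rng = np.random.default_rng(seed)
    n = model.n_fibers
    first = np.exp(np.log(model.median_um) + model.log_sd * rng.normal(size=n))
    factor = model.stall_factor if treated else 1.0
    second = first * factor * np.exp(model.ratio_log_sd * rng.normal(size=n))
    df = pd.DataFrame(
        {
            "fiber_id": [f"{model.group}_{'HU_' if treated else ''}f{i+1}" for i in range(n)],
            "idu_length_um": first,
            "cldu_length_um": second,
            "group": model.group,
            "hu_treated": bool(treated),
        }
    )
    return FiberTable(table=df)
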