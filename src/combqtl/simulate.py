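"""Synthetic advanced-intercross data with known ground truth.

Emulates the study system: an F8 advanced intercross between two
differentially fixed founder lines (Red Junglefowl "R" x White Leghorn
"W") genotyped on an evenly spaced cM map, with quantitative phenotypes
carrying planted additive/dominance QTL plus sex, batch, family and
weight covariate effects; closed comb-like outlines whose shape depends
on genotype; and expression traits with planted cis and trans eQTL.

Meiosis follows Haldane's model (crossovers without interference), which
matches the map function used by the scan engine.  Breeding is random
mating of distinct dam/sire pairs with uniform litter sizes; the family
identity of the final generation's parents serves as the "population
structure" covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cross import CrossData, GeneticMap, GENOTYPE_CODES
from .morphometrics import EFACoefficients, Outline, efa_reconstruct

_LITTER_CAP = 20  # max offspring per breeding pair per generation


@dataclass
class SimConfig:
    """Scale parameters of the simulated intercross.

    ``n_generations`` counts generations including the founders, so 2
    yields the F1 and the default of 9 yields an F8 population.  The
    default map (5 chromosomes x 200 cM, 10 cM spacing, 300 individuals)
    is a scaled-down version of the study design; :func:`full_scale_config`
    gives the study-scale map (~9,200 cM at ~16 cM spacing, 326 F8 birds).
    """

    n_chromosomes: int = 5
    chr_length: float = 200.0
    marker_spacing: float = 10.0
    n_generations: int = 9
    n_founder_pairs: int = 20
    n_individuals: int = 300
    n_breeding_pairs: int = 30
    seed: int = 0
    bp_per_cm: float = 300_000.0

    def __post_init__(self) -> None:
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be positive")
        if self.chr_length < self.marker_spacing:
            raise ValueError("chr_length must be at least marker_spacing")
        if self.n_generations < 2:
            raise ValueError("need n_generations >= 2 (founders + F1)")
        if self.n_chromosomes < 1 or self.n_founder_pairs < 1:
            raise ValueError("n_chromosomes and n_founder_pairs must be >= 1")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.n_breeding_pairs < 1:
            raise ValueError("need at least one breeding pair")
        if self.n_individuals > _LITTER_CAP * min(self.n_founder_pairs, self.n_breeding_pairs):
            raise ValueError(
                f"{self.n_individuals} individuals cannot be bred from "
                f"{min(self.n_founder_pairs, self.n_breeding_pairs)} pairs "
                f"without selfing (litter cap {_LITTER_CAP})"
            )

    @property
    def f_generation(self) -> int:
        return self.n_generations - 1


def full_scale_config(seed: int = 0) -> SimConfig:
    """Study-scale design: 10 x 920 cM chromosomes, 16 cM spacing, 326 F8."""
    return SimConfig(
        n_chromosomes=10, chr_length=920.0, marker_spacing=16.0,
        n_generations=9, n_founder_pairs=20, n_individuals=326, seed=seed,
    )


@dataclass
class QTLSpec:
    """A planted quantitative trait locus."""

    chromosome: str
    position: float
    additive_effect: float = 0.0
    dominance_effect: float = 0.0
    trait_name: str = "trait"


@dataclass
class ExpressionSpec:
    """Design of a planted expression architecture.

    ``probe_positions`` maps probe id -> (chromosome, cM).  Probes listed
    in ``cis_probes`` get a cis effect of ``cis_effect_size`` at the
    marker nearest their own position; ``trans_pairs`` entries
    ``(probe_id, chromosome, cM, effect)`` add effects from a regulator
    elsewhere on the map.
    """

    probe_positions: dict
    cis_probes: tuple = ()
    cis_effect_size: float = 0.0
    trans_pairs: tuple = ()
    batch_effect_sd: float = 0.0
    noise_sd: float = 1.0
    n_batches: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if len(self.probe_positions) < 1:
            raise ValueError("need at least one probe")
        unknown = set(self.cis_probes) - set(self.probe_positions)
        if unknown:
            raise ValueError(f"cis_probes not in probe_positions: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Map and genotypes


def simulate_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced marker grid; bp = cM x ``bp_per_cm``."""
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        pos = np.arange(0.0, config.chr_length + 1e-9, config.marker_spacing)
        for j, cm in enumerate(pos):
            rows.append((f"c{c}m{j + 1}", str(c), float(cm), int(round(cm * config.bp_per_cm))))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"]))


@dataclass
class MarkerGenotypes:
    """Simulated genotypes with breeding ground truth.

    ``codes``: (n_individuals, n_markers) int8 array, RR=0, RW=1, WW=2.
    ``family``: final-generation parental pair id per individual.
    """

    gmap: GeneticMap
    codes: np.ndarray
    family: np.ndarray
    generation: int

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    def to_frame(self) -> pd.DataFrame:
        lut = np.array(GENOTYPE_CODES, dtype=object)
        return pd.DataFrame(
            lut[self.codes], columns=self.gmap.marker_names,
            index=[f"ind{i + 1}" for i in range(self.n_individuals)],
        )

    def additive_dosage(self, marker: str) -> np.ndarray:
        """x_a in {-1, 0, +1}: W allele count minus 1."""
        j = self.gmap.marker_names.index(marker)
        return self.codes[:, j].astype(float) - 1.0

    def dominance_indicator(self, marker: str) -> np.ndarray:
        j = self.gmap.marker_names.index(marker)
        return (self.codes[:, j] == 1).astype(float)


def _meiosis(haps: np.ndarray, parent_idx: np.ndarray, r: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Gametes from ``haps`` (n_parents, m, 2) for each row of parent_idx.

    Phase along the chromosome is a 2-state Markov chain switching with
    the Haldane recombination fraction between adjacent markers — exact
    for crossovers without interference.
    """
    n_off, m = len(parent_idx), haps.shape[1]
    p_switch = np.concatenate([[0.5], r])  # random start phase
    switches = rng.random((n_off, m)) < p_switch
    phase = np.cumsum(switches, axis=1) % 2
    cols = np.arange(m)
    return haps[parent_idx[:, None], cols[None, :], phase]


def _breed_pairs(n_parents: int, n_offspring: int, rng: np.random.Generator,
                 max_pairs: int):
    """Distinct dam/sire pairs with uniform litter sizes; no selfing."""
    order = rng.permutation(n_parents)
    n_pairs = min(max(n_parents // 2, 1), max_pairs)
    dams = order[:n_pairs]
    sires = order[n_pairs:2 * n_pairs] if n_parents >= 2 else order[:1]
    # round-robin assignment keeps litter sizes uniform (differ by <= 1)
    pair_of = rng.permutation(np.arange(n_offspring) % n_pairs)
    return dams[pair_of], sires[pair_of], pair_of


def simulate_ail_genotypes(gmap: GeneticMap, config: SimConfig,
                           rng: np.random.Generator | None = None) -> MarkerGenotypes:
    """Breed the intercross forward and genotype the final generation.

    Founders are differentially fixed (line R all-RR, line W all-WW), so
    the F1 is fully heterozygous; subsequent generations are produced by
    random mating, accumulating recombinations that expand the map.
    """
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    from .qtl import haldane_recomb

    pop = config.n_individuals
    chrom_haps = {}
    recomb = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        recomb[chrom] = haldane_recomb(np.diff(pos))
        m = len(pos)
        # F1: one R haplotype, one W haplotype each
        haps = np.zeros((pop, m, 2), dtype=np.int8)
        haps[:, :, 1] = 1
        chrom_haps[chrom] = haps
    family = np.zeros(pop, dtype=int)
    # generation 2 is the F1 built above; breed forward to n_generations.
    # Intermediate generations pair the whole pool (equalized litters keep
    # drift low); the final mapping generation is expanded from
    # n_breeding_pairs litters, which define the family covariate.
    for gen in range(3, config.n_generations + 1):
        final = gen == config.n_generations
        max_pairs = config.n_breeding_pairs if final else max(pop // 2, 1)
        dams, sires, pair_of = _breed_pairs(pop, pop, rng, max_pairs)
        for chrom in gmap.chromosomes:
            haps = chrom_haps[chrom]
            g1 = _meiosis(haps, dams, recomb[chrom], rng)
            g2 = _meiosis(haps, sires, recomb[chrom], rng)
            chrom_haps[chrom] = np.stack([g1, g2], axis=2)
        family = pair_of
    codes = np.concatenate(
        [chrom_haps[c].sum(axis=2, dtype=np.int8) for c in gmap.chromosomes], axis=1
    )
    return MarkerGenotypes(gmap=gmap, codes=codes, family=family,
                           generation=config.f_generation)


# ---------------------------------------------------------------------------
# Quantitative traits


@dataclass
class PhenotypeTable:
    """Simulated phenotypes with their covariates and true genetic values."""

    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    genetic_values: pd.DataFrame


def default_covariates(n: int, family: np.ndarray, rng: np.random.Generator,
                       n_batches: int = 4, weight_mean: float = 1800.0,
                       weight_sd: float = 250.0) -> pd.DataFrame:
    """Balanced sex and batch, family from the pedigree, Gaussian weight."""
    sex = np.tile([0, 1], n // 2 + 1)[:n]
    batch = np.tile(np.arange(n_batches), n // n_batches + 1)[:n]
    weight = rng.normal(weight_mean, weight_sd, size=n)
    return pd.DataFrame({
        "sex": rng.permutation(sex),
        "batch": pd.Categorical(rng.permutation(batch)),
        "family": pd.Categorical(family),
        "weight": weight,
    }, index=[f"ind{i + 1}" for i in range(n)])


def simulate_quantitative_trait(genotypes: MarkerGenotypes, gmap: GeneticMap,
                                qtls, covariate_effects: dict | None = None,
                                noise_sd: float = 1.0,
                                rng: np.random.Generator | None = None,
                                seed: int | None = None,
                                mean: float = 0.0,
                                covariates: pd.DataFrame | None = None) -> PhenotypeTable:
    """Phenotypes from planted QTL + covariate effects + Gaussian noise.

    Each QTL contributes ``a * x_a + d * x_d`` at the marker nearest its
    position.  ``covariate_effects`` maps covariate name to a coefficient
    (numeric covariates: slope; ``sex``: shift for sex==1; ``batch`` and
    ``family``: SD of per-level Gaussian effects).  QTL with the same
    ``trait_name`` share one phenotype column.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    if covariates is None:
        covariates = default_covariates(n, genotypes.family, rng)
    eff = dict(covariate_effects or {})
    cov_term = np.zeros(n)
    for name, coef in eff.items():
        if name not in covariates.columns:
            raise KeyError(f"unknown covariate {name!r}")
        col = covariates[name].to_numpy()
        if name in ("batch", "family"):
            levels, inv = np.unique(col, return_inverse=True)
            cov_term += rng.normal(0.0, coef, size=len(levels))[inv]
        else:
            cov_term += coef * col.astype(float)

    by_trait: dict[str, list] = {}
    for q in qtls:
        by_trait.setdefault(q.trait_name, []).append(q)
    phen, gvals = {}, {}
    for trait, specs in by_trait.items() or {"trait": []}.items():
        g = np.zeros(n)
        for q in specs:
            if str(q.chromosome) not in [str(c) for c in gmap.chromosomes]:
                raise ValueError(f"QTL chromosome {q.chromosome!r} not on map")
            if not 0 <= q.position <= gmap.chrom_length(str(q.chromosome)):
                raise ValueError(f"QTL position {q.position} off chromosome {q.chromosome}")
            mk = gmap.nearest_marker(str(q.chromosome), q.position)["marker"]
            g += (q.additive_effect * genotypes.additive_dosage(mk)
                  + q.dominance_effect * genotypes.dominance_indicator(mk))
        phen[trait] = mean + g + cov_term + rng.normal(0.0, noise_sd, size=n)
        gvals[trait] = g
    if not phen:  # no QTL specified: pure-noise trait
        phen["trait"] = mean + cov_term + rng.normal(0.0, noise_sd, size=n)
        gvals["trait"] = np.zeros(n)
    idx = covariates.index
    return PhenotypeTable(
        phenotypes=pd.DataFrame(phen, index=idx),
        covariates=covariates,
        genetic_values=pd.DataFrame(gvals, index=idx),
    )


def noise_sd_for_pve(genetic_values: np.ndarray, target_pve: float) -> float:
    """Noise SD making a planted QTL explain ``target_pve`` of variance.

    Solves var(g) / (var(g) + sd^2) = target_pve for the realized genetic
    values of this population.
    """
    if not 0 < target_pve < 1:
        raise ValueError("target_pve must be in (0, 1)")
    var_g = float(np.var(np.asarray(genetic_values, float)))
    if var_g <= 0:
        raise ValueError("genetic values have zero variance")
    return float(np.sqrt(var_g * (1.0 / target_pve - 1.0)))


def to_cross(genotypes: MarkerGenotypes, table: PhenotypeTable) -> CrossData:
    """Bundle simulated genotypes + phenotypes into scan-ready CrossData."""
    return CrossData(
        gmap=genotypes.gmap,
        genotypes=genotypes.to_frame(),
        phenotypes=table.phenotypes,
        covariates=table.covariates,
    )


# ---------------------------------------------------------------------------
# Expression


@dataclass
class SimulatedExpression:
    """Expression matrix with probe annotation and planted ground truth."""

    values: pd.DataFrame          # probes x individuals
    annotation: pd.DataFrame      # probe, chrom, cM, bp
    batch: pd.Series              # per-individual batch label
    truth: pd.DataFrame           # probe, label (cis/trans/none), effect columns


def simulate_expression_matrix(genotypes: MarkerGenotypes, gmap: GeneticMap,
                               spec: ExpressionSpec,
                               rng: np.random.Generator | None = None,
                               seed: int | None = None) -> SimulatedExpression:
    """Expression traits with planted cis and trans eQTL plus batch noise.

    expression[p, j] = baseline_p + cis dose term (marker nearest the
    probe) + trans dose terms + batch effect + N(0, noise_sd).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    chrom_ids = {str(c) for c in gmap.chromosomes}
    for pid, (chrom, cm) in spec.probe_positions.items():
        if str(chrom) not in chrom_ids:
            raise ValueError(f"probe {pid!r} on unknown chromosome {chrom!r}")
    probes = list(spec.probe_positions)
    batch = np.tile(np.arange(spec.n_batches), n // spec.n_batches + 1)[:n]
    batch = rng.permutation(batch)
    batch_eff = rng.normal(0.0, spec.batch_effect_sd, size=(len(probes), spec.n_batches))
    trans_by_probe: dict[str, list] = {}
    for pid, chrom, cm, effect in spec.trans_pairs:
        if pid not in spec.probe_positions:
            raise ValueError(f"trans pair names unknown probe {pid!r}")
        if str(chrom) not in chrom_ids:
            raise ValueError(f"trans regulator on unknown chromosome {chrom!r}")
        trans_by_probe.setdefault(pid, []).append((str(chrom), cm, effect))

    values = np.empty((len(probes), n))
    truth_rows = []
    for i, pid in enumerate(probes):
        chrom, cm = spec.probe_positions[pid]
        baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
        expr = np.full(n, baseline) + batch_eff[i, batch]
        label = "none"
        if pid in spec.cis_probes and spec.cis_effect_size != 0.0:
            mk = gmap.nearest_marker(str(chrom), cm)["marker"]
            expr += spec.cis_effect_size * genotypes.additive_dosage(mk)
            label = "cis"
        for (tchrom, tcm, effect) in trans_by_probe.get(pid, []):
            mk = gmap.nearest_marker(tchrom, tcm)["marker"]
            expr += effect * genotypes.additive_dosage(mk)
            label = "trans" if label == "none" else label
        expr += rng.normal(0.0, spec.noise_sd, size=n)
        values[i] = expr
        truth_rows.append((pid, label))

    ind_ids = [f"ind{i + 1}" for i in range(n)]
    annot = pd.DataFrame(
        [(pid, str(c), float(cm), int(round(cm * 300_000))) for pid, (c, cm) in spec.probe_positions.items()],
        columns=["probe", "chrom", "cM", "bp"],
    )
    return SimulatedExpression(
        values=pd.DataFrame(values, index=probes, columns=ind_ids),
        annotation=annot,
        batch=pd.Series(batch, index=ind_ids, name="batch"),
        truth=pd.DataFrame(truth_rows, columns=["probe", "label"]),
    )


# ---------------------------------------------------------------------------
# Outlines


def simulate_outline_population(genotypes: MarkerGenotypes, shape_qtl: QTLSpec,
                                mean_coeffs: EFACoefficients,
                                effect_vector: np.ndarray,
                                noise_sd: float = 0.0, n_points: int = 200,
                                rng: np.random.Generator | None = None,
                                seed: int | None = None) -> list:
    """Outlines whose Fourier coefficients shift with allele dose.

    Individual i's coefficient vector is ``mean + dose_i * effect + eps_i``
    with ``eps_i ~ N(0, noise_sd)`` per coefficient, rendered by inverse
    EFA at ``n_points``; the planted shape axis is recoverable by the
    trace -> align -> EFA -> PCA -> scan chain.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    power = mean_coeffs.power()
    if mean_coeffs.n_harmonics < 1 or power[0] <= 0:
        raise ValueError("mean coefficients need non-zero first-harmonic power")
    mk = genotypes.gmap.nearest_marker(str(shape_qtl.chromosome), shape_qtl.position)["marker"]
    dose = genotypes.additive_dosage(mk)
    base = mean_coeffs.flatten()
    effect_vector = np.asarray(effect_vector, float)
    if effect_vector.shape != base.shape:
        raise ValueError("effect_vector must match the flattened coefficient length")
    outlines = []
    for d in dose:
        vec = base + d * effect_vector + rng.normal(0.0, noise_sd, size=base.shape)
        outlines.append(efa_reconstruct(
            EFACoefficients.from_flat(vec, A0=mean_coeffs.A0, C0=mean_coeffs.C0), n_points))
    return outlines


def render_outline_mask(outline: Outline, resolution: int = 512) -> np.ndarray:
    """Rasterize a closed outline to a binary silhouette image.

    The outline is centered and isotropically scaled so its larger extent
    spans 90% of the image; mimics the black-on-white comb silhouettes
    the tracing step consumes.
    """
    from skimage.draw import polygon

    if resolution < 16:
        raise ValueError("resolution must be at least 16")
    area = abs(outline.signed_area())
    extent = np.ptp(outline.points, axis=0)
    if area <= 1e-12 * max(float(extent.max()), 1.0) ** 2:
        raise ValueError("outline has (near-)zero area; nothing to render")
    pts = outline.points - outline.points.mean(axis=0)
    scale = 0.45 * resolution / (extent.max() / 2.0)
    rr_f = pts[:, 1] * scale + resolution / 2.0
    cc_f = pts[:, 0] * scale + resolution / 2.0
    mask = np.zeros((resolution, resolution), dtype=bool)
    rr, cc = polygon(rr_f, cc_f, shape=mask.shape)
    mask[rr, cc] = True
    return mask
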