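"""Synthetic plaque-tissue generator.

Emulates the data model of an imaging-based spatial transcriptomics run
segmented with a Baysor-style algorithm: per-cell centroids, areas and
segmentation-QC fields, per-transcript coordinates with Phred-like quality
scores and assignment confidences, a cell x gene count matrix, and
pathologist-style subregion polygons.

The tissue is a disc with concentric annular subregions (lumen, necrotic
core, fibrous cap, intima, media for plaques; lumen, intima, media for
controls).  Cell substates are planted in radial bands, which gives every
downstream stage — subregion assignment, neighbourhood clustering, lumen
layering — a known ground truth to recover.  Distributional choices (negative
binomial counts scaled by cell area, Beta confidences, lognormal areas,
uniform noise over the disc) are plausible stand-ins, not fitted to any real
dataset; see docs/methods.md for what they do and do not emulate.

Determinism: one global seed; each sample draws from a child generator
keyed by (seed, sample index), so individual samples can be regenerated
without replaying the whole cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from plaquespace.types import (
    ConfigError,
    CountTable,
    SubregionAnnotation,
    SyntheticSample,
)

# Radial layout of the plaque disc, as fractions of the tissue radius.
# Controls lack the necrotic core and fibrous cap; their intima spans the
# corresponding zone.
PLAQUE_LAYOUT = {
    "lumen": (0.0, 0.20),
    "necrotic_core": (0.20, 0.45),
    "fibrous_cap": (0.45, 0.60),
    "intima": (0.60, 0.80),
    "media": (0.80, 1.00),
}
CONTROL_LAYOUT = {
    "lumen": (0.0, 0.20),
    "intima": (0.20, 0.80),
    "media": (0.80, 1.00),
}

CIRCLE_VERTICES = 64


@dataclass(frozen=True)
class SubstateSpec:
    """One cell substate: its radial placement band and gene program.

    ``band`` is (inner, outer) as fractions of the tissue radius; cells of
    the substate are placed uniformly (by area) within the band.  ``program``
    is the mean transcript count per gene for a cell of average area.
    """

    label: str
    band: tuple[float, float]
    program: tuple[float, ...]


def _default_substates(n_genes: int) -> list[SubstateSpec]:
    """Five substates layered lumen-to-adventitia, eight marker genes each.

    Markers sit at mean 3 counts/cell, a shared housekeeping block at 1,
    everything else at 0.05 — roughly the sparsity of a targeted in situ
    panel.
    """
    labels_bands = [
        ("EC_lumen", (0.20, 0.28)),
        ("Mac_TREM2hi", (0.28, 0.45)),
        ("Mac_C1Q", (0.45, 0.60)),
        ("VSMC_modul", (0.60, 0.80)),
        ("VSMC_contr", (0.80, 1.00)),
    ]
    n_markers = 8
    needed = len(labels_bands) * n_markers + 10
    if n_genes < needed:
        raise ConfigError(f"default catalogue needs n_genes >= {needed}")
    out = []
    for i, (label, band) in enumerate(labels_bands):
        program = np.full(n_genes, 0.05)
        program[i * n_markers : (i + 1) * n_markers] = 3.0
        program[len(labels_bands) * n_markers : len(labels_bands) * n_markers + 10] = 1.0
        out.append(SubstateSpec(label, band, tuple(program)))
    return out


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Defaults describe a small but realistic cohort: 6 samples of 1200 cells
    on a 1 mm-radius tissue disc with a 200 µm lumen, a targeted panel of 60
    genes, 10% noise transcripts, and Beta(12, 2) assignment confidences
    (mode ≈ 0.92, matching well-segmented tissue).
    """

    n_samples: int = 6
    n_controls: int = 2
    cells_per_sample: int = 1200
    n_genes: int = 60
    substates: list[SubstateSpec] | None = None
    substate_proportions: dict[str, float] | None = None
    nb_dispersion: float = 2.0
    area_lognormal_params: tuple[float, float] = (math.log(150.0), 0.35)
    confidence_beta_params: tuple[float, float] = (12.0, 2.0)
    max_cluster_frac_beta_params: tuple[float, float] = (40.0, 1.5)
    lifespan_lognormal_params: tuple[float, float] = (math.log(200.0), 0.5)
    noise_transcript_rate: float = 0.10
    low_q_fraction: float = 0.05
    tissue_radius_um: float = 1000.0
    lumen_radius_um: float = 200.0
    band_jitter: float = 0.0
    fraction_shift_substate: str | None = None
    fraction_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substates is None:
            self.substates = _default_substates(self.n_genes)
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not 0 <= self.n_controls <= self.n_samples:
            raise ConfigError("n_controls must be in [0, n_samples]")
        if self.cells_per_sample < 1:
            raise ConfigError("cells_per_sample must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0 <= self.noise_transcript_rate < 1:
            raise ConfigError("noise_transcript_rate must be in [0, 1)")
        if not 0 <= self.low_q_fraction < 1:
            raise ConfigError("low_q_fraction must be in [0, 1)")
        if self.tissue_radius_um <= 0 or self.lumen_radius_um <= 0:
            raise ConfigError("radii must be positive")
        if self.lumen_radius_um >= self.tissue_radius_um:
            raise ConfigError("lumen radius must be smaller than tissue radius")
        lumen_frac = self.lumen_radius_um / self.tissue_radius_um
        for spec in self.substates:
            inner, outer = spec.band
            if not inner < outer:
                raise ConfigError(
                    f"substate {spec.label!r}: band inner must be < outer"
                )
            if inner < lumen_frac - 1e-9 or outer > 1 + 1e-9:
                raise ConfigError(
                    f"substate {spec.label!r}: band must lie within "
                    f"[lumen_radius/tissue_radius, 1]"
                )
            if len(spec.program) > self.n_genes:
                raise ConfigError("gene program longer than n_genes")
        labels = [s.label for s in self.substates]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate substate labels")
        if self.substate_proportions is not None:
            extra = set(self.substate_proportions) - set(labels)
            if extra:
                raise ConfigError(f"proportions for unknown substates: {extra}")
        if self.fraction_shift_substate is not None:
            if self.fraction_shift_substate not in labels:
                raise ConfigError("fraction_shift_substate not in catalogue")
            if not -1 < self.fraction_shift < 1:
                raise ConfigError("fraction_shift must be in (-1, 1)")


def _circle(radius: float, n: int = CIRCLE_VERTICES) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


def _region_polygons(config: SimConfig, sample_id: str, condition: str) -> list[SubregionAnnotation]:
    layout = PLAQUE_LAYOUT if condition == "plaque" else CONTROL_LAYOUT
    R = config.tissue_radius_um
    polys = []
    for region, (inner, outer) in layout.items():
        if inner == 0.0:
            polys.append(SubregionAnnotation(sample_id, region, _circle(outer * R)))
        else:
            polys.append(
                SubregionAnnotation(
                    sample_id, region, _circle(outer * R), holes=[_circle(inner * R)]
                )
            )
    return polys


def _proportions(config: SimConfig, condition: str) -> np.ndarray:
    labels = [s.label for s in config.substates]
    if config.substate_proportions is not None:
        p = np.array([config.substate_proportions.get(l, 0.0) for l in labels])
    else:
        p = np.ones(len(labels))
    p = p / p.sum()
    if config.fraction_shift_substate is not None and condition == "plaque":
        i = labels.index(config.fraction_shift_substate)
        p[i] = max(p[i] + config.fraction_shift, 0.0)
        p = p / p.sum()
    return p


def _sample_rng(config: SimConfig, sample_index: int) -> np.random.Generator:
    # child stream keyed by (seed, index): regenerating sample k alone gives
    # the same draws as generating the whole cohort
    return np.random.default_rng(np.random.SeedSequence([config.seed, sample_index]))


def generate_sample(
    config: SimConfig,
    sample_id: str,
    condition: str = "plaque",
    sample_index: int = 0,
) -> SyntheticSample:
    """Generate one tissue sample.

    Cells are assigned a substate (categorical draw with the configured
    proportions), placed uniformly-by-area in the substate's radial band
    (plus optional Gaussian radial jitter of ``band_jitter`` x tissue
    radius), given a lognormal area and Beta-distributed QC fields.  Counts
    are negative binomial with mean = program mean x (cell area / mean
    area); the transcript table is the exact expansion of the count matrix,
    so assigned transcripts and counts conserve by construction.  Noise
    transcripts (confidence 0, no cell id) are scattered uniformly over the
    tissue disc at the configured rate.
    """
    config.validate()
    rng = _sample_rng(config, sample_index)
    n = config.cells_per_sample
    R = config.tissue_radius_um
    specs = config.substates
    labels = np.array([s.label for s in specs])

    substate_idx = rng.choice(len(specs), size=n, p=_proportions(config, condition))

    inner = np.array([s.band[0] for s in specs])[substate_idx] * R
    outer = np.array([s.band[1] for s in specs])[substate_idx] * R
    u = rng.random(n)
    r = np.sqrt(u * (outer**2 - inner**2) + inner**2)
    if config.band_jitter > 0:
        r = r + rng.normal(0.0, config.band_jitter * R, size=n)
        r = np.clip(r, config.lumen_radius_um, R)
    theta = rng.random(n) * 2 * np.pi
    x, y = r * np.cos(theta), r * np.sin(theta)

    mu_a, sd_a = config.area_lognormal_params
    areas = rng.lognormal(mu_a, sd_a, size=n)
    mean_area = math.exp(mu_a + sd_a**2 / 2)

    a_c, b_c = config.confidence_beta_params
    conf = rng.beta(a_c, b_c, size=n)
    a_m, b_m = config.max_cluster_frac_beta_params
    mcf = rng.beta(a_m, b_m, size=n)
    mu_l, sd_l = config.lifespan_lognormal_params
    lifespan = rng.lognormal(mu_l, sd_l, size=n)

    cell_ids = np.array([f"{sample_id}_c{i:05d}" for i in range(n)])
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": sample_id,
            "x_um": x,
            "y_um": y,
            "area_um2": areas,
            "substate": labels[substate_idx],
            "avg_assignment_confidence": conf,
            "max_cluster_frac": mcf,
            "lifespan": lifespan,
        }
    )

    # counts: NB(mean = program * area / mean_area, shared dispersion)
    programs = np.zeros((len(specs), config.n_genes))
    for i, s in enumerate(specs):
        programs[i, : len(s.program)] = s.program
    mu = programs[substate_idx] * (areas / mean_area)[:, None]
    theta_disp = config.nb_dispersion
    p_nb = theta_disp / (theta_disp + mu)
    counts = rng.negative_binomial(theta_disp, p_nb)
    genes = np.array([f"g{j:03d}" for j in range(config.n_genes)])
    count_df = pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"), columns=genes)

    transcripts = _emit_transcripts(rng, config, cells, count_df, genes)

    polygons = _region_polygons(config, sample_id, condition)
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "substate": labels[substate_idx],
            "band_inner": inner / R,
            "band_outer": outer / R,
        }
    )
    return SyntheticSample(
        sample_id=sample_id,
        condition=condition,
        cells=cells,
        transcripts=transcripts,
        counts=CountTable(count_df, normalized=False),
        polygons=polygons,
        truth=truth,
    )


def _emit_transcripts(rng, config, cells, count_df, genes) -> pd.DataFrame:
    counts = count_df.to_numpy()
    cell_rep, gene_rep = np.nonzero(counts)
    reps = counts[cell_rep, gene_rep]
    cell_of_tx = np.repeat(cell_rep, reps)
    gene_of_tx = np.repeat(gene_rep, reps)
    n_tx = len(cell_of_tx)

    # scatter transcripts around their cell centroid at ~half the cell radius
    sigma = np.sqrt(cells["area_um2"].to_numpy() / np.pi) / 2.0
    tx_x = cells["x_um"].to_numpy()[cell_of_tx] + rng.normal(0, sigma[cell_of_tx])
    tx_y = cells["y_um"].to_numpy()[cell_of_tx] + rng.normal(0, sigma[cell_of_tx])

    def draw_q(m: int) -> np.ndarray:
        low = rng.random(m) < config.low_q_fraction
        q = rng.uniform(20.0, 40.0, size=m)
        q[low] = rng.uniform(10.0, 20.0, size=low.sum())
        return q

    assigned = pd.DataFrame(
        {
            "gene": genes[gene_of_tx],
            "x_um": tx_x,
            "y_um": tx_y,
            "qscore": draw_q(n_tx),
            "cell_id": cells["cell_id"].to_numpy()[cell_of_tx],
            "assignment_confidence": rng.beta(8.0, 2.0, size=n_tx),
        }
    )

    rate = config.noise_transcript_rate
    n_noise = int(round(rate / (1 - rate) * n_tx)) if rate > 0 else 0
    if n_noise:
        rr = config.tissue_radius_um * np.sqrt(rng.random(n_noise))
        tt = rng.random(n_noise) * 2 * np.pi
        noise = pd.DataFrame(
            {
                "gene": rng.choice(genes, size=n_noise),
                "x_um": rr * np.cos(tt),
                "y_um": rr * np.sin(tt),
                "qscore": draw_q(n_noise),
                "cell_id": pd.array([pd.NA] * n_noise, dtype=object),
                "assignment_confidence": np.zeros(n_noise),
            }
        )
        out = pd.concat([assigned, noise], ignore_index=True)
    else:
        out = assigned
    return out


def generate_cohort(config: SimConfig) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate a cohort of samples plus a metadata table.

    The first ``n_controls`` samples are controls (geometry without necrotic
    core and fibrous cap); the rest are plaques.  Metadata carries the
    condition and a binary covariate (``symptomatic``) for association
    tests, drawn from the cohort-level seed.
    """
    config.validate()
    meta_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10**6]))
    samples = []
    rows = []
    for i in range(config.n_samples):
        condition = "control" if i < config.n_controls else "plaque"
        sid = f"S{i:02d}"
        samples.append(generate_sample(config, sid, condition, sample_index=i))
        rows.append(
            {
                "sample_id": sid,
                "patient_id": f"P{i:02d}",
                "condition": condition,
                "symptomatic": int(meta_rng.random() < 0.5),
            }
        )
    return samples, pd.DataFrame(rows)


def shuffle_labels_null(sample: SyntheticSample, seed: int) -> SyntheticSample:
    """Return a copy of ``sample`` with substate labels permuted uniformly.

    Coordinates, counts, polygons and the planted truth stay untouched; the
    label multiset is preserved.  This is the within-sample null used by the
    neighbourhood-enrichment permutation machinery.
    """
    if len(sample.cells) < 1:
        raise ValueError("sample has no cells")
    rng = np.random.default_rng(seed)
    cells = sample.cells.copy()
    cells["substate"] = rng.permutation(cells["substate"].to_numpy())
    return replace(sample, cells=cells)


# ---------------------------------------------------------------------------
# purpose-built scenario helpers used by the planted-recovery analyses


def generate_domain_sample(
    n_cells: int,
    sample_id: str,
    seed: int,
    n_domains: int = 3,
    substates_per_domain: int = 2,
    tissue_radius_um: float = 1000.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Plant ``n_domains`` compositional spatial domains on a disc.

    Domains are equal angular sectors (pie slices); each has its own
    disjoint pool of substates, so local neighbourhood composition
    identifies the domain.  Returns the cell table and the planted domain
    label per cell.
    """
    rng = np.random.default_rng(seed)
    domain = rng.integers(0, n_domains, size=n_cells)
    r = tissue_radius_um * np.sqrt(rng.random(n_cells))
    width = 2 * np.pi / n_domains
    theta = domain * width + rng.random(n_cells) * width
    sub_local = rng.integers(0, substates_per_domain, size=n_cells)
    substate = np.array(
        [f"s{d * substates_per_domain + j}" for d, j in zip(domain, sub_local)]
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_c{i:05d}" for i in range(n_cells)],
            "sample_id": sample_id,
            "x_um": r * np.cos(theta),
            "y_um": r * np.sin(theta),
            "area_um2": 150.0,
            "substate": substate,
        }
    )
    return cells, domain


def generate_archetype_cohort(
    archetypes: list[dict[str, float]],
    samples_per_archetype: int,
    cells_per_sample: int,
    seed: int,
    base_config: SimConfig | None = None,
) -> tuple[list[SyntheticSample], np.ndarray]:
    """Cohort with planted composition archetypes for morphological clustering.

    Each archetype is a substate->proportion mapping; samples of an archetype
    draw their cells with those proportions (multinomial noise only).
    Returns the samples and the true archetype index per sample.
    """
    cfg = base_config or SimConfig(seed=seed, cells_per_sample=cells_per_sample)
    samples, truth = [], []
    idx = 0
    for a, props in enumerate(archetypes):
        for _ in range(samples_per_archetype):
            c = replace(
                cfg,
                substate_proportions=props,
                cells_per_sample=cells_per_sample,
                seed=seed,
            )
            samples.append(generate_sample(c, f"A{a}_S{idx:02d}", sample_index=idx))
            truth.append(a)
            idx += 1
    return samples, np.array(truth)
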