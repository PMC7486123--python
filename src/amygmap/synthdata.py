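"""Synthetic-data generators emulating the BLA study's statistical structure.

Every downstream stage of the pipeline is exercisable without any download:

* :func:`gen_counts` draws negative-binomial scRNA-seq counts for two
  discrete excitatory populations (27%/73% by default) with 415 planted
  differential genes — half binary on/off, half partially penetrant — plus a
  1-D latent gradient within each population driving graded marker genes.
* :func:`gen_spatial_cells` emits per-cell mFISH-style tables over a section
  template: a sharp Negr1/Cplx1 transition across the LA-BA border, smooth
  within-region marker gradients, and a small interneuron-like "spill-over"
  contingent carrying the opposite discrete marker.
* :func:`gen_projection_cells` samples projection-labeled cell positions as
  a truncated isotropic Gaussian clipped to a named nucleus.
* :func:`gen_image_stack` builds paired image stacks of analytic disks for
  the segmentation and FFT-registration stages.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, box

from .containers import CountMatrix
from .spatial_register import RegionTemplate

#: the 12-gene multiplexed FISH panel
MFISH_PANEL = [
    "Nr4a2", "Otof", "Cdh13", "Rorb", "Adamts2", "Prss23",
    "Bdnf", "Slc5a5", "Slc17a7", "Nnat", "Negr1", "Cplx1",
]

#: panel genes with smooth spatial gradients (everything but the two
#: discrete nucleus markers and the excitatory gate gene)
GRADIENT_PANEL = [g for g in MFISH_PANEL if g not in ("Negr1", "Cplx1", "Slc17a7")]


# ---------------------------------------------------------------------------
# section templates

# Hand-digitised intermediate-section BLA outline, um, origin at the
# dorsal-most point, y increasing ventrally. Qualitatively egg-shaped with
# the narrow pole dorsal; no claim of atlas fidelity.
_BASE_OUTLINE = np.array([
    (0, 0), (260, 60), (460, 220), (560, 450), (590, 720), (560, 1000),
    (440, 1250), (260, 1420), (40, 1490), (-180, 1450), (-340, 1300),
    (-430, 1080), (-450, 820), (-400, 560), (-280, 320), (-120, 120),
], dtype=float)

# slanted LA/BA border, dorsal LA above, running medial-high to lateral-low
_BASE_BORDER = np.array([(-700.0, 620.0), (800.0, 380.0)])

# canonical six landmarks: dorsal tip, dorsolateral shoulder, lateral
# bulge, ventral tip, medial bulge, dorsomedial shoulder
_BASE_LANDMARKS = np.array([
    (0, 0), (460, 220), (590, 720), (40, 1490), (-450, 820), (-280, 320),
], dtype=float)

_SECTION_SCALE = {"anterior": 0.85, "intermediate": 1.0, "posterior": 1.08}

SECTIONS = tuple(_SECTION_SCALE)


def _halfplane_split(outline: Polygon, border: np.ndarray) -> tuple[Polygon, Polygon, LineString]:
    (x0, y0), (x1, y1) = border
    minx, miny, maxx, maxy = outline.bounds
    big = box(minx - 1, miny - 1, maxx + 1, maxy + 1)
    # signed side of the border line: positive below (ventral, BA)
    dx, dy = x1 - x0, y1 - y0
    above = Polygon([(x0 - 10 * dx, y0 - 10 * dy - 1e5), (x1 + 10 * dx, y1 + 10 * dy - 1e5),
                     (x1 + 10 * dx, y1 + 10 * dy), (x0 - 10 * dx, y0 - 10 * dy)])
    la = outline.intersection(above.intersection(big))
    ba = outline.difference(above)
    return la, ba, LineString(border)


def default_template(section: str = "intermediate") -> RegionTemplate:
    """The package's versioned BLA section template.

    Three sections (anterior / intermediate / posterior) share one
    hand-digitised shape at slightly different scales. The BA carries two
    optional subregions (dorsal/ventral) split at 60% of its height.
    """
    if section not in _SECTION_SCALE:
        raise ValueError(f"unknown section {section!r}; choose from {SECTIONS}")
    s = _SECTION_SCALE[section]
    outline_xy = _BASE_OUTLINE * s
    border = _BASE_BORDER * s
    outline = Polygon(outline_xy)
    la, ba, _ = _halfplane_split(outline, border)
    # BA subregions: split at a horizontal line through 60% of BA's extent
    bminx, bminy, bmaxx, bmaxy = ba.bounds
    ysplit = bminy + 0.6 * (bmaxy - bminy)
    upper = box(bminx - 1, bminy - 1, bmaxx + 1, ysplit)
    subregions = {
        "BA_dorsal": ba.intersection(upper),
        "BA_ventral": ba.difference(upper),
    }
    return RegionTemplate(
        section=section,
        outline=outline,
        la=la,
        ba=ba,
        landmarks=_BASE_LANDMARKS * s,
        subregions=subregions,
    )


def border_line(template: RegionTemplate) -> LineString:
    """The LA/BA border polyline of a template built by :func:`default_template`."""
    s = _SECTION_SCALE[template.section]
    return LineString(_BASE_BORDER * s)


def signed_border_distance(template: RegionTemplate, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance to the LA/BA border, negative on the LA (dorsal) side."""
    line = border_line(template)
    pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
    d = shapely.distance(line, pts)
    (x0, y0), (x1, y1) = np.asarray(line.coords)
    side = (x1 - x0) * (np.asarray(y, float) - y0) - (y1 - y0) * (np.asarray(x, float) - x0)
    return np.where(side > 0, d, -d)


# ---------------------------------------------------------------------------
# scRNA-seq simulation


@dataclass
class ScSimConfig:
    """Configuration for the two-population scRNA-seq count simulator.

    Defaults emulate the study conditions: 1231 excitatory neurons at a
    27/73 split, 415 planted differential genes (half on/off, half
    partially penetrant), log-normal library sizes around 2e5 counts, and
    negative-binomial gene-wise noise.
    """

    n_cells: int = 1231
    prop_pop1: float = 0.27
    n_genes: int = 12000
    n_de_genes: int = 415
    frac_onoff: float = 0.5
    n_gradient_genes_per_pop: int = 40
    depth_mean_log: float = math.log(2e5)
    depth_sd_log: float = 0.35
    nb_dispersion: float = 2.0
    baseline_sigma: float = 2.5
    onoff_ratio: float = 50.0
    penetrance: float = 0.6
    penetrant_fold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prop_pop1 < 1.0):
            raise ValueError("prop_pop1 must lie strictly inside (0, 1)")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if min(self.n_cells, self.n_genes) < 1:
            raise ValueError("counts must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_de_genes < 0 or self.n_gradient_genes_per_pop < 0:
            raise ValueError("gene counts must be non-negative")


@dataclass
class ScSimTruth:
    """Ground truth of a simulated count matrix."""

    population: pd.Series          # 0 (majority, BA-like) or 1 (minority, LA-like) per cell
    u: pd.Series                   # latent within-population gradient in [0, 1]
    de_gene_ids: list[str]
    onoff_gene_ids: list[str]
    penetrant_gene_ids: list[str]
    de_enriched_pop: pd.Series     # per DE gene: population it is enriched in
    gradient_gene_ids: dict[int, list[str]] = field(default_factory=dict)


def null_config(seed: int = 0, **kwargs) -> ScSimConfig:
    """Planted-null configuration: identical populations, no DE, no gradients."""
    return ScSimConfig(n_de_genes=0, n_gradient_genes_per_pop=0, seed=seed, **kwargs)


def gen_counts(cfg: ScSimConfig) -> tuple[CountMatrix, ScSimTruth]:
    """Draw a gene x cell negative-binomial count matrix with planted structure.

    Gene-wise means are a log-normal baseline re-shaped by the planted
    differential and gradient effects, scaled to log-normal library sizes,
    and sampled as gamma-Poisson (negative binomial with shape
    ``nb_dispersion``). Two housekeeping-style gate genes, Snap25 (high
    everywhere) and Gad1 (near zero — all simulated cells are excitatory),
    are included so the class-gating stage runs end to end.
    """
    rng = np.random.default_rng(cfg.seed)
    n_g, n_c = cfg.n_genes, cfg.n_cells
    pop = (rng.random(n_c) < cfg.prop_pop1).astype(int)  # 1 = minority/LA-like
    u = rng.random(n_c)

    genes = np.array([f"g{i:05d}" for i in range(n_g)], dtype=object)
    # baseline relative expression in approximate CPM units
    w = rng.lognormal(0.0, cfg.baseline_sigma, n_g)
    rel = np.repeat((w / w.sum() * 1e6)[:, None], n_c, axis=1)

    # reserve two non-DE genes as gate genes with fixed expression
    special = rng.choice(n_g, size=2 + cfg.n_de_genes + 2 * cfg.n_gradient_genes_per_pop,
                         replace=False)
    snap_i, gad_i = special[:2]
    genes[snap_i], genes[gad_i] = "Snap25", "Gad1"
    rel[snap_i] = 1500.0
    rel[gad_i] = 5.0

    de_idx = special[2: 2 + cfg.n_de_genes]
    n_onoff = int(round(cfg.frac_onoff * cfg.n_de_genes))
    onoff_idx = de_idx[:n_onoff]
    pen_idx = de_idx[n_onoff:]
    enriched = rng.integers(0, 2, size=cfg.n_de_genes)

    in_pop = [pop == 0, pop == 1]
    for j, gi in enumerate(onoff_idx):
        c_on = rng.uniform(20.0, 60.0)
        on_pop = enriched[j]
        rel[gi, in_pop[on_pop]] = c_on
        rel[gi, in_pop[1 - on_pop]] = c_on / cfg.onoff_ratio
    for j, gi in enumerate(pen_idx):
        c_base = rng.uniform(1.0, 5.0)
        on_pop = enriched[n_onoff + j]
        rel[gi] = c_base
        mask = in_pop[on_pop] & (rng.random(n_c) < cfg.penetrance)
        rel[gi, mask] = c_base * cfg.penetrant_fold

    grad_ids: dict[int, list[str]] = {0: [], 1: []}
    g_off = 2 + cfg.n_de_genes
    for p in (0, 1):
        idx = special[g_off + p * cfg.n_gradient_genes_per_pop:
                      g_off + (p + 1) * cfg.n_gradient_genes_per_pop]
        grad_ids[p] = [str(genes[i]) for i in idx]
        for gi in idx:
            c_base = rng.uniform(10.0, 40.0)
            mid = rng.uniform(0.2, 0.8)
            slope = rng.uniform(4.0, 10.0)
            f = 0.5 + 1.5 / (1.0 + np.exp(-slope * (u - mid)))
            sel = in_pop[p]
            # mean-normalise within the population so the gene is graded
            # but not differentially expressed between populations
            f = f / f[sel].mean()
            rel[gi, sel] = c_base * f[sel]
            rel[gi, ~sel] = c_base

    depth = rng.lognormal(cfg.depth_mean_log, cfg.depth_sd_log, n_c)
    mu = rel / rel.sum(axis=0, keepdims=True) * depth[None, :]
    # pan-neuronal/interneuron gate genes behave like housekeeping genes:
    # far less bursty than the typical gene, so gating is clean
    r = np.full(n_g, cfg.nb_dispersion)
    r[[snap_i, gad_i]] = 25.0
    lam = rng.gamma(r[:, None], mu / r[:, None])
    counts = rng.poisson(lam).astype(np.int32)

    cells = pd.Index([f"cell{i:04d}" for i in range(n_c)], name="cell")
    cm = CountMatrix(pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cells))
    truth = ScSimTruth(
        population=pd.Series(pop, index=cells, name="population"),
        u=pd.Series(u, index=cells, name="u"),
        de_gene_ids=[str(genes[i]) for i in de_idx],
        onoff_gene_ids=[str(genes[i]) for i in onoff_idx],
        penetrant_gene_ids=[str(genes[i]) for i in pen_idx],
        de_enriched_pop=pd.Series(enriched, index=[str(genes[i]) for i in de_idx]),
        gradient_gene_ids=grad_ids,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# spatial mFISH simulation


@dataclass
class SpatialSimConfig:
    """Configuration for the per-section mFISH cell-table simulator.

    ``border_sharpness`` is the logistic slope (per um) of the discrete
    Negr1/Cplx1 transition across the LA-BA border; ``math.inf`` gives a
    perfectly sharp step. Gradient genes vary logistically along per-gene
    axes spanning the template. CPA noise is additive Gaussian truncated
    at zero.
    """

    template: RegionTemplate = None  # type: ignore[assignment]
    n_cells_per_section: int = 1000
    marker_panel: tuple[str, ...] = tuple(MFISH_PANEL)
    border_sharpness: float = 0.04
    discrete_amplitude: float = 0.08
    gradient_amplitude: float = 0.05
    slc17a7_level: float = 0.05
    noise_sd: float = 0.008
    spillover_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template is None:
            self.template = default_template("intermediate")
        if self.template.outline.area <= 0:
            raise ValueError("degenerate template")
        if not (0.0 <= self.spillover_rate < 1.0):
            raise ValueError("spillover_rate must lie in [0, 1)")


def _uniform_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 64)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, x, y)
        out = np.vstack([out, np.column_stack([x, y])[keep]])
    return out[:n]


def _gradient_profiles(cfg: SpatialSimConfig) -> dict[str, tuple[np.ndarray, float, float]]:
    """Per-gene (unit axis, logistic midpoint, slope), seeded from the config."""
    rng = np.random.default_rng(cfg.seed + 7919)
    profiles = {}
    grad_genes = [g for g in cfg.marker_panel if g in GRADIENT_PANEL]
    for i, g in enumerate(grad_genes):
        # spread axes over the half-circle; jitter with the seeded rng
        theta = math.pi * (i / max(len(grad_genes), 1)) + rng.normal(0, 0.15)
        axis = np.array([math.cos(theta), math.sin(theta)])
        mid = rng.uniform(0.25, 0.75)
        slope = rng.uniform(4.0, 9.0)
        profiles[g] = (axis, mid, slope)
    return profiles


def gen_spatial_cells(cfg: SpatialSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one section's per-cell CPA table plus ground truth.

    Returns ``(cells, truth)``: ``cells`` has columns ``cell_id, section,
    x_um, y_um, area_um2`` and one CPA column per panel gene; ``truth``
    records the atlas-side label and the interneuron-like spill-over flag.
    Spill-over cells carry the opposite discrete marker at full level and
    sub-gate Slc17a7.
    """
    rng = np.random.default_rng(cfg.seed)
    tpl = cfg.template
    n = cfg.n_cells_per_section
    xy = _uniform_in_polygon(tpl.outline, n, rng)
    d = signed_border_distance(tpl, xy[:, 0], xy[:, 1])  # >0 on BA side
    area = np.clip(rng.normal(180.0, 40.0, n), 80.0, 400.0)

    A = cfg.discrete_amplitude
    k = cfg.border_sharpness
    if math.isinf(k):
        ba_side = (d > 0).astype(float)
        cplx_base = A * ba_side
        negr_base = A * (1.0 - ba_side)
    else:
        cplx_base = A / (1.0 + np.exp(-k * d))
        negr_base = A / (1.0 + np.exp(k * d))

    spill = rng.random(n) < cfg.spillover_rate
    # spill-over cells express the wrong side's marker at full level and,
    # being interneuron-like, essentially no Slc17a7 (well below the gate)
    negr = np.where(spill, np.where(d > 0, A, 0.0), negr_base)
    cplx = np.where(spill, np.where(d > 0, 0.0, A), cplx_base)
    slc = np.where(spill, 0.0005, cfg.slc17a7_level)

    minx, miny, maxx, maxy = tpl.outline.bounds
    span = np.array([maxx - minx, maxy - miny])
    profiles = _gradient_profiles(cfg)
    values: dict[str, np.ndarray] = {}
    for g in cfg.marker_panel:
        if g == "Negr1":
            base = negr
        elif g == "Cplx1":
            base = cplx
        elif g == "Slc17a7":
            base = slc
        else:
            axis, mid, slope = profiles[g]
            t = ((xy - np.array([minx, miny])) / span) @ axis
            t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
            base = cfg.gradient_amplitude * (0.15 + 0.85 / (1.0 + np.exp(-slope * (t - mid))))
        noisy = base + rng.normal(0.0, cfg.noise_sd, n)
        if g == "Slc17a7":  # gate gene: low noise so the 0.004 CPA gate is clean
            noisy = base + rng.normal(0.0, cfg.noise_sd / 8.0, n)
        values[g] = np.clip(noisy, 0.0, None)

    cells = pd.DataFrame({
        "cell_id": [f"{tpl.section[:3]}_{i:04d}" for i in range(n)],
        "section": tpl.section,
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "area_um2": area,
    })
    for g in cfg.marker_panel:
        cells[g] = values[g]
    truth = pd.DataFrame({
        "cell_id": cells["cell_id"],
        "true_region": np.where(d > 0, "BA", "LA"),
        "interneuron_like": spill,
        "border_distance_um": d,
    })
    return cells, truth


def gen_all_sections(cfg: SpatialSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate anterior + intermediate + posterior sections in one table."""
    frames, truths = [], []
    for i, sec in enumerate(SECTIONS):
        sub = replace(cfg, template=default_template(sec), seed=cfg.seed + i)
        c, t = gen_spatial_cells(sub)
        frames.append(c)
        truths.append(t)
    return pd.concat(frames, ignore_index=True), pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# projection-labeled cells


def gen_projection_cells(
    template: RegionTemplate,
    region: str,
    subregion_center: tuple[float, float],
    spread_um: float,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample projection-labeled cell positions in a nucleus.

    Positions follow an isotropic Gaussian of scale ``spread_um`` around
    ``subregion_center``, truncated to the named region's polygon
    (``spread_um=inf`` gives the uniform distribution over the region).
    ``n=0`` returns an empty table.
    """
    poly = {"LA": template.la, "BA": template.ba}.get(region)
    if poly is None:
        raise ValueError(f"region must be 'LA' or 'BA', got {region!r}")
    cx, cy = subregion_center
    if not shapely.contains_xy(template.outline, cx, cy):
        raise ValueError("subregion_center lies outside the template outline")
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 2))
    if n > 0 and math.isinf(spread_um):
        pts = _uniform_in_polygon(poly, n, rng)
    else:
        while len(pts) < n:
            m = max(4 * (n - len(pts)), 64)
            cand = rng.normal(loc=(cx, cy), scale=spread_um, size=(m, 2))
            keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
            pts = np.vstack([pts, cand[keep]])
        pts = pts[:n]
    return pd.DataFrame({
        "cell_id": [f"proj_{i:04d}" for i in range(n)],
        "x_um": pts[:, 0] if n else np.array([]),
        "y_um": pts[:, 1] if n else np.array([]),
        "region": region,
    })


# ---------------------------------------------------------------------------
# toy image stacks


@dataclass
class DiskSpec:
    """An analytic disk ROI: centre (um), radius (um), intensity."""

    x_um: float
    y_um: float
    radius_um: float
    intensity: float = 1.0

    @property
    def area_um2(self) -> float:
        return math.pi * self.radius_um**2


def render_disks(
    disks: list[DiskSpec],
    shape: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Rasterise disks onto a 2-D float image (y, x) at ``pixel_size_um``."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    img = np.zeros(shape, dtype=float)
    for d in disks:
        cx, cy, r = d.x_um / pixel_size_um, d.y_um / pixel_size_um, d.radius_um / pixel_size_um
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        img[mask] = np.maximum(img[mask], d.intensity)
    return img


def gen_image_stack(
    disks: list[DiskSpec],
    shape: tuple[int, int, int] = (12, 128, 128),
    pixel_size_um: float = 1.0,
    shift: tuple[int, int, int] = (0, 0, 0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a base stack of disks plus a translated copy for registration tests.

    The copy is shifted by integer ``(dz, dy, dx)`` pixels with wrap-around
    (circular translation), so integer phase-correlation recovery is exact;
    optional Gaussian noise of ``noise_sd`` is added independently to both
    stacks. Disks span the central third of the z-extent. A shift whose
    magnitude reaches the stack size is rejected.
    """
    nz, ny, nx = shape
    dz, dy, dx = shift
    if abs(dz) >= nz or abs(dy) >= ny or abs(dx) >= nx:
        raise ValueError(f"shift {shift} exceeds stack shape {shape}")
    plane = render_disks(disks, (ny, nx), pixel_size_um)
    base = np.zeros(shape, dtype=float)
    z0, z1 = nz // 3, max(nz // 3 + 1, 2 * nz // 3)
    base[z0:z1] = plane
    moved = np.roll(base, (dz, dy, dx), axis=(0, 1, 2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        base = base + rng.normal(0.0, noise_sd, shape)
        moved = moved + rng.normal(0.0, noise_sd, shape)
    return base, moved
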