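"""Seeded generators for every input the analysis consumes.

Three layers of synthetic data, matched to the statistical structure the
pipeline assumes rather than to embryo morphology:

* enhancer-length DNA with PWM instances planted at known positions and a
  rejection step guaranteeing no accidental library-motif hit elsewhere;
* dual-reporter intensity tables with per-embryo electroporation
  efficiency (log-normal, shared by both channels), per-cell transgene
  mosaicism (correlated reporter/control uptake by default, since
  co-electroporated plasmids co-segregate), and multiplicative log-normal
  cell noise;
* small renderable image stacks of Gaussian nuclear blobs with matching
  notochord ROI polygons, for exercising the projection/ROI code path.

Every generator takes a seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import MotifLibrary
from .motifs import BASES, reverse_complement
from .reporter import EmbryoMeasurement, ImageStack, ROISet
from .scan import MotifHit, ScanConfig, scan_sequence

__all__ = [
    "Plant",
    "SequenceSimConfig",
    "ConstructSpec",
    "ExpressionSimConfig",
    "GroundTruth",
    "generate_enhancer",
    "simulate_measurements",
    "simulate_cells",
    "RenderCell",
    "render_stack",
]


@dataclass(frozen=True)
class Plant:
    """One motif instance to embed: 1-based start, strand, consensus or sampled."""

    motif_id: str
    position: int
    strand: str = "+"
    mode: str = "consensus"  # or "sample"


@dataclass
class SequenceSimConfig:
    """Background + plants for one synthetic enhancer.

    Defaults: 377 bp (the length of the proximal enhancer fragment the
    assay dissects) and 35% GC, typical of AT-rich tunicate non-coding
    sequence.  ``exclusion_threshold`` is the scan p-value at which
    accidental background hits are rejected and the sequence resampled.
    """

    length: int = 377
    gc_content: float = 0.35
    plants: list[Plant] = field(default_factory=list)
    exclusion_threshold: float = 1e-3
    allow_overlap: bool = False
    seed: int = 0
    max_attempts: int = 200


@dataclass
class GroundTruth:
    """What the generator actually put in, for recall/recovery checks."""

    planted_hits: list[MotifHit] = field(default_factory=list)
    efficiencies: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    blob_integrals: pd.DataFrame | None = None


def _background_probs(gc: float) -> np.ndarray:
    if not (0 < gc < 1):
        raise ValueError("gc_content must be in (0, 1)")
    at = (1 - gc) / 2
    return np.array([at, gc / 2, gc / 2, at])


def _plant_window(plant: Plant, library: MotifLibrary, rng: np.random.Generator) -> str:
    pwm = library.pwms[plant.motif_id]
    if plant.mode == "consensus":
        window = pwm.consensus()
    elif plant.mode == "sample":
        probs = pwm.probabilities()
        window = "".join(
            BASES[rng.choice(4, p=probs[:, j])] for j in range(pwm.width)
        )
    else:
        raise ValueError(f"unknown plant mode {plant.mode!r}")
    if plant.strand == "-":
        window = reverse_complement(window)
    return window


def generate_enhancer(
    cfg: SequenceSimConfig, library: MotifLibrary
) -> tuple[str, GroundTruth]:
    """I.i.d. background with planted motif instances, rejection-cleaned.

    Rejection-resamples the background until no library motif matches at
    the exclusion threshold outside the planted intervals (hits
    overlapping a planted interval — e.g. the strand-symmetric image of a
    plant — are tolerated).  Resampling is local: only the bases of an
    offending window are redrawn on each pass, which converges far faster
    than redrawing the whole sequence while leaving the accepted
    background i.i.d. outside the plants.  Raises after ``max_attempts``
    passes without convergence.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = _background_probs(cfg.gc_content)
    intervals = []
    windows = []
    for plant in cfg.plants:
        pwm = library.pwms[plant.motif_id]
        s0, e0 = plant.position - 1, plant.position - 1 + pwm.width
        if s0 < 0 or e0 > cfg.length:
            raise ValueError(f"plant {plant.motif_id} at {plant.position} outside sequence")
        if not cfg.allow_overlap:
            for (os0, oe0, _) in intervals:
                if s0 < oe0 and os0 < e0:
                    raise ValueError(
                        f"plant {plant.motif_id} at {plant.position} overlaps another plant; "
                        "set allow_overlap=True if intended"
                    )
        intervals.append((s0, e0, plant))
        windows.append(_plant_window(plant, library, rng))

    planted = np.zeros(cfg.length, dtype=bool)
    for s0, e0, _ in intervals:
        planted[s0:e0] = True

    scan_cfg = ScanConfig(p_threshold=cfg.exclusion_threshold)
    chars = [BASES[i] for i in rng.choice(4, size=cfg.length, p=probs)]
    for (s0, e0, _), window in zip(intervals, windows):
        chars[s0:e0] = window
    for _attempt in range(cfg.max_attempts):
        seq = "".join(chars)
        offending = np.zeros(cfg.length, dtype=bool)
        for lom in library.loms.values():
            for h in scan_sequence(seq, lom, cfg=scan_cfg):
                s0, e0 = h.interval0()
                overlaps_plant = any(s0 < pe and ps < e0 for ps, pe, _ in intervals)
                if not overlaps_plant:
                    offending[s0:e0] = True
        offending &= ~planted
        if not offending.any():
            truth = GroundTruth(
                planted_hits=[
                    MotifHit(
                        motif_id=p.motif_id, seq_id="synthetic", start=s0 + 1, end=e0,
                        strand=p.strand, score=float("nan"), p_value=float("nan"),
                        matched_seq=seq[s0:e0],
                    )
                    for (s0, e0, p) in intervals
                ]
            )
            return seq, truth
        for idx in np.nonzero(offending)[0]:
            chars[idx] = BASES[int(rng.choice(4, p=probs))]
    raise RuntimeError(
        f"no clean background in {cfg.max_attempts} passes; "
        "use a longer sequence or a looser exclusion threshold"
    )


@dataclass(frozen=True)
class ConstructSpec:
    """One reporter construct: relative strength, mosaicism, lineage bias.

    ``strength`` multiplies the per-cell expressed reporter intensity
    (wildtype = 1); ``mosaicism`` is the probability that a transfected
    cell expresses the reporter; ``secondary_attenuation`` multiplies
    reporter output in secondary-lineage cells only.
    """

    construct_id: str
    strength: float = 1.0
    mosaicism: float = 1.0
    secondary_attenuation: float = 1.0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if not (0 <= self.mosaicism <= 1):
            raise ValueError("mosaicism must be in [0, 1]")


@dataclass
class ExpressionSimConfig:
    """Generative model for the dual-reporter measurements.

    Noise defaults emulate the qualitative spread of a real
    electroporation series: embryo efficiency E_j ~ LogNormal(0, 1) —
    several-fold between embryos — and per-cell multiplicative noise
    LogNormal(0, 1), which after averaging over 32 + 8 notochord cells
    leaves most wildtype normalized ratios between roughly 0.5 and 2.
    Expressed intensities are ``scale * strength * E_j * noise`` on the
    reporter channel and ``control_scale * E_j * noise`` on the control
    channel; non-expressing cells emit the constant staining baseline.
    Reporter/control uptake is maximally correlated by default (one
    uptake event per cell); ``correlated_uptake=False`` makes the two
    channels' mosaicism independent.
    """

    constructs: list[ConstructSpec] = field(default_factory=lambda: [ConstructSpec("WT")])
    n_embryos: int = 10
    n_replicates: int = 3
    efficiency_sigma: float = 1.0
    cell_sigma: float = 1.0
    baseline: float = 32.0
    reporter_scale: float = 2000.0
    control_scale: float = 2000.0
    control_mosaicism: float = 1.0
    n_primary: int = 32
    n_secondary: int = 8
    correlated_uptake: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.efficiency_sigma < 0 or self.cell_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not (0 <= self.control_mosaicism <= 1):
            raise ValueError("control_mosaicism must be in [0, 1]")


def _simulate_cell_table(cfg: ExpressionSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(cfg.seed)
    rows = []
    eff_rows = []
    n_cells = cfg.n_primary + cfg.n_secondary
    for rep in range(1, cfg.n_replicates + 1):
        for c in cfg.constructs:
            for e in range(1, cfg.n_embryos + 1):
                embryo_id = f"{c.construct_id}_r{rep}_e{e}"
                eff = float(rng.lognormal(0.0, cfg.efficiency_sigma))
                eff_rows.append(
                    {"embryo_id": embryo_id, "replicate_id": f"rep{rep}",
                     "construct_id": c.construct_id, "efficiency": eff}
                )
                u = rng.random(n_cells)
                if cfg.correlated_uptake:
                    rep_on = u < c.mosaicism
                    ctl_on = u < cfg.control_mosaicism
                else:
                    rep_on = u < c.mosaicism
                    ctl_on = rng.random(n_cells) < cfg.control_mosaicism
                eps_r = rng.lognormal(0.0, cfg.cell_sigma, n_cells)
                eps_c = rng.lognormal(0.0, cfg.cell_sigma, n_cells)
                lineage = np.array(
                    ["primary"] * cfg.n_primary + ["secondary"] * cfg.n_secondary
                )
                atten = np.where(lineage == "secondary", c.secondary_attenuation, 1.0)
                reporter = np.where(
                    rep_on,
                    cfg.reporter_scale * c.strength * atten * eff * eps_r,
                    cfg.baseline,
                )
                control = np.where(
                    ctl_on, cfg.control_scale * eff * eps_c, cfg.baseline
                )
                for i in range(n_cells):
                    rows.append(
                        {
                            "cell_id": f"{embryo_id}_c{i + 1}",
                            "embryo_id": embryo_id,
                            "replicate_id": f"rep{rep}",
                            "construct_id": c.construct_id,
                            "lineage": lineage[i],
                            "reporter_mean": float(reporter[i]),
                            "control_mean": float(control[i]),
                            "reporter_expressed": bool(rep_on[i]),
                            "control_expressed": bool(ctl_on[i]),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(eff_rows)


def simulate_cells(cfg: ExpressionSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell dual-reporter intensities before any embryo averaging."""
    cells, eff = _simulate_cell_table(cfg)
    return cells, GroundTruth(efficiencies=eff, cells=cells)


def simulate_measurements(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Embryo-level measurement table aggregated from simulated cells.

    Returns a DataFrame with the columns :func:`cisquant.reporter.normalize_experiment`
    expects (whole-notochord and per-lineage channel means) plus the
    ground truth (per-embryo efficiencies and the underlying cell table).
    """
    cells, truth = simulate_cells(cfg)
    rows = []
    for embryo_id, grp in cells.groupby("embryo_id", sort=False):
        prim = grp[grp["lineage"] == "primary"]
        sec = grp[grp["lineage"] == "secondary"]
        rows.append(
            {
                "embryo_id": embryo_id,
                "replicate_id": grp["replicate_id"].iloc[0],
                "construct_id": grp["construct_id"].iloc[0],
                "reporter_mean": grp["reporter_mean"].mean(),
                "control_mean": grp["control_mean"].mean(),
                "reporter_primary": prim["reporter_mean"].mean() if len(prim) else np.nan,
                "control_primary": prim["control_mean"].mean() if len(prim) else np.nan,
                "reporter_secondary": sec["reporter_mean"].mean() if len(sec) else np.nan,
                "control_secondary": sec["control_mean"].mean() if len(sec) else np.nan,
            }
        )
    return pd.DataFrame(rows), truth


@dataclass(frozen=True)
class RenderCell:
    """One nucleus to render: 3D centroid plus per-channel blob mass."""

    x: float
    y: float
    z: float
    reporter: float
    control: float
    lineage: str = "primary"


def _gaussian_blob(shape, center, sigma) -> np.ndarray:
    z, y, x = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    cz, cy, cx = center
    g = np.exp(
        -((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2) / (2.0 * sigma**2)
    )
    return g / g.sum()


def render_stack(
    cells: list[RenderCell],
    shape: tuple[int, int, int] = (8, 48, 96),
    sigma: float = 1.5,
    poisson_noise: bool = False,
    roi_margin: float = 5.0,
    seed: int = 0,
) -> tuple[ImageStack, ROISet, GroundTruth]:
    """Render nuclei as Gaussian blobs and emit matching ROI polygons.

    Each blob is normalized over the volume, so its sum projection
    integrates to exactly the cell's channel intensity (up to edge
    truncation).  ROI rectangles cover the whole cell set and, when both
    lineages are present, the primary and secondary subsets.
    """
    nz, ny, nx = shape
    volume = np.zeros((2, nz, ny, nx))
    integrals = []
    for c in cells:
        if not (0 <= c.z < nz and 0 <= c.y < ny and 0 <= c.x < nx):
            raise ValueError(f"centroid ({c.x}, {c.y}, {c.z}) outside volume {shape}")
        blob = _gaussian_blob(shape, (c.z, c.y, c.x), sigma)
        volume[0] += c.reporter * blob
        volume[1] += c.control * blob
        integrals.append(
            {"x": c.x, "y": c.y, "z": c.z, "lineage": c.lineage,
             "reporter": c.reporter, "control": c.control}
        )
    if poisson_noise:
        rng = np.random.default_rng(seed)
        volume = rng.poisson(volume).astype(float)

    def rect(subset: list[RenderCell]) -> np.ndarray | None:
        if not subset:
            return None
        xs = [c.x for c in subset]
        ys = [c.y for c in subset]
        m = roi_margin
        x0, x1 = max(min(xs) - m, -0.5), min(max(xs) + m, nx - 0.5)
        y0, y1 = max(min(ys) - m, -0.5), min(max(ys) + m, ny - 0.5)
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])

    primary = [c for c in cells if c.lineage == "primary"]
    secondary = [c for c in cells if c.lineage == "secondary"]
    rois = ROISet(
        whole=rect(cells) if cells else np.array([[-0.5, -0.5], [nx - 0.5, -0.5], [nx - 0.5, ny - 0.5], [-0.5, ny - 0.5]]),
        primary=rect(primary) if primary and secondary else None,
        secondary=rect(secondary) if primary and secondary else None,
    )
    stack = ImageStack(voxels=volume, channel_roles={"reporter": 0, "control": 1})
    return stack, rois, GroundTruth(blob_integrals=pd.DataFrame(integrals))
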