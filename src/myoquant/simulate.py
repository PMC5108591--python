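"""Synthetic fluorescence-microscopy scenes and per-cell outcome tables.

This module fabricates the two kinds of raw material the rest of the
package consumes, with known ground truth:

* **Scenes** — multi-channel fields of view containing mononucleated
  myoblasts (elliptical cytoplasm of programmable eccentricity) and
  multinucleated myotubes (elongated capsules holding 2–40+ nuclei),
  rendered into a nuclear channel, a cytoplasm channel and one channel
  per marker, and corrupted with additive Gaussian noise, a smooth
  low-frequency background gradient, and small saturated speckle
  artifacts.  Every cell's geometry, nucleus positions and marker
  states are recorded in a truth table.

* **Outcome tables** — per-cell Bernoulli outcomes drawn from a
  logistic model with factorial effects (intercept µ, per-factor
  log-odds β, optional dose slope c) and a per-group random intercept
  u_g ~ N(0, σ_g²), i.e. exactly the data-generating process a
  random-intercept logistic regression assumes.  A companion generator
  draws overdispersed counts (variance = dispersion × mean) for
  quasi-Poisson modelling.

Randomness is split into three sub-streams derived from the single
scene seed (geometry = 0, markers = 1, noise/rendering = 2) so that,
for example, changing the noise level never moves a cell.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import PlacementError, ValidationError
from .frames import ImageFrame, write_frame

# Nuclei-count classes for myotubes: small 2–4, medium 5–9, large 10–24,
# very large 25+ (capped at MAX_NUCLEI for rendering).
SIZE_CLASS_RANGES: tuple[tuple[int, int], ...] = ((2, 4), (5, 9), (10, 24), (25, 40))
MAX_NUCLEI = 40

_CYTO_LEVEL = 0.55   # nominal cytoplasm intensity, fraction of full scale
_NUC_LEVEL = 0.75    # nominal nuclear intensity
_MAX_ATTEMPTS = 1000


@dataclass
class SceneParams:
    """Parameters of one synthetic field of view.

    ``eccentricity_mean``/``eccentricity_sd`` govern mononucleated
    cells (truncated normal on [0, 0.93]).  ``myotube_fraction`` is the
    per-cell probability of being a myotube, whose nucleus count is
    drawn from ``nuclei_count_weights`` over the four size classes.
    Alternatively, setting ``fusion_probability`` switches to a
    nucleus-level model: ``n_nuclei_total`` nuclei are each fused with
    that probability and fused nuclei are grouped into myotubes, so the
    scene's true fusion index is an exact binomial draw.
    ``marker_probs`` gives Bernoulli positivity per marker; a marker
    named ``myhc`` is forced positive on myotubes (myotubes are
    MyHC-positive by construction of the assay).
    """

    field_size: tuple[int, int] = (768, 768)
    n_cells: int = 100
    eccentricity_mean: float = 0.6
    eccentricity_sd: float = 0.1
    myotube_fraction: float = 0.0
    nuclei_count_weights: tuple[float, ...] = (0.45, 0.30, 0.20, 0.05)
    marker_probs: dict[str, float] = field(default_factory=dict)
    background_amplitude: float = 0.3
    speckle_density: float = 5.0   # artifacts per megapixel, per channel
    noise_sd: float = 0.02         # additive Gaussian, fraction of full scale
    seed: int = 0
    # geometry knobs
    cell_radius: float = 16.0      # geometric-mean semi-axis of myoblasts, px
    nucleus_radius: float = 6.0
    min_separation: float = 3.0    # clearance between cell outlines, px
    # nucleus-level fusion mode (overrides myotube_fraction when set)
    fusion_probability: float | None = None
    n_nuclei_total: int | None = None
    # annotations carried into the truth table and frame metadata
    condition: str = "control"
    dose: float = 0.0
    group: str = "g1"

    def __post_init__(self):
        probs = {
            "myotube_fraction": self.myotube_fraction,
            **{f"marker_probs[{k}]": v for k, v in self.marker_probs.items()},
        }
        if self.fusion_probability is not None:
            probs["fusion_probability"] = self.fusion_probability
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} = {p} is not a probability in [0, 1]")
        if not (0.0 <= self.eccentricity_mean < 1.0):
            raise ValidationError("eccentricity_mean must lie in [0, 1)")
        if self.eccentricity_sd < 0:
            raise ValidationError("eccentricity_sd must be >= 0")
        w = np.asarray(self.nuclei_count_weights, dtype=float)
        if w.shape != (4,) or (w < 0).any():
            raise ValidationError("nuclei_count_weights must be 4 non-negative weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"nuclei_count_weights must sum to 1 (got {w.sum():.12f})"
            )
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.noise_sd < 0 or self.background_amplitude < 0 or self.speckle_density < 0:
            raise ValidationError("noise/background/speckle parameters must be >= 0")


@dataclass
class TruthCell:
    """Ground truth for one generated cell."""

    cell_id: int
    centre: tuple[float, float]        # (row, col)
    a: float                           # semi-major axis, px
    b: float                           # semi-minor axis, px
    theta: float                       # orientation, radians
    eccentricity: float                # sqrt(1 - (b/a)^2)
    nuclei: np.ndarray                 # (k, 2) nucleus centres, (row, col)
    markers: dict[str, bool]
    is_myotube: bool

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)


@dataclass
class SyntheticScene:
    """A generated field of view: cells, rendered frame, and truth table."""

    params: SceneParams
    cells: list[TruthCell]
    frame: ImageFrame
    truth_table: pd.DataFrame
    # speckle artifact ground truth: channel -> (n, 3) rows of (row, col, radius)
    speckles: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def true_fusion_index(self) -> float:
        """Nuclei in multinucleated cells over all nuclei, from the truth."""
        total = sum(c.n_nuclei for c in self.cells)
        fused = sum(c.n_nuclei for c in self.cells if c.n_nuclei >= 2)
        return fused / total if total else float("nan")


# ---------------------------------------------------------------------------
# geometry helpers

def _unit(theta: float) -> np.ndarray:
    # direction of the major axis in (row, col) coordinates
    return np.array([math.sin(theta), math.cos(theta)])


def _axis_points(centre, half_len, theta, step=4.0):
    """Sample points along a capsule centre line for overlap testing."""
    u = _unit(theta)
    n = max(int(math.ceil(half_len / step)), 1)
    t = np.linspace(-half_len, half_len, 2 * n + 1)
    return np.asarray(centre) + t[:, None] * u


class _Placer:
    """Rejection-sampling placement of capsules with clearance.

    Each cell is summarised by centre-line sample points and a radius;
    a candidate is rejected when any of its points comes within
    (r1 + r2 + separation + sampling slack) of a placed point.  The
    4-px slack makes the sampled test conservative, so accepted layouts
    never overlap.
    """

    def __init__(self, shape, separation):
        self.shape = shape
        self.sep = separation
        self._pts: list[np.ndarray] = []
        self._rad: list[np.ndarray] = []

    def try_place(self, rng, half_len, radius):
        h, w = self.shape
        for _ in range(_MAX_ATTEMPTS):
            theta = rng.uniform(0.0, math.pi)
            u = _unit(theta)
            ext = np.abs(u) * half_len + radius + 2.0
            if ext[0] >= h / 2 or ext[1] >= w / 2:
                continue  # cell longer than the field at this angle
            centre = np.array(
                [rng.uniform(ext[0], h - ext[0]), rng.uniform(ext[1], w - ext[1])]
            )
            pts = _axis_points(centre, half_len, theta)
            if self._pts:
                allp = np.concatenate(self._pts)
                allr = np.concatenate(self._rad)
                d = np.sqrt(((pts[:, None, :] - allp[None, :, :]) ** 2).sum(-1))
                if (d < allr[None, :] + radius + self.sep + 4.0).any():
                    continue
            self._pts.append(pts)
            self._rad.append(np.full(len(pts), radius))
            return centre, theta
        return None


# ---------------------------------------------------------------------------
# scene generation

def _draw_myotube_counts(rng, n_tubes, weights):
    counts = []
    classes = rng.choice(len(SIZE_CLASS_RANGES), size=n_tubes, p=weights)
    for c in classes:
        lo, hi = SIZE_CLASS_RANGES[c]
        counts.append(int(rng.integers(lo, hi + 1)))
    return counts


def _partition_fused(rng, n_fused, weights):
    """Split a pool of fused nuclei into myotube sizes drawn from the classes."""
    sizes = []
    remaining = n_fused
    while remaining >= 2:
        lo, hi = SIZE_CLASS_RANGES[rng.choice(len(SIZE_CLASS_RANGES), p=weights)]
        k = int(rng.integers(lo, hi + 1))
        if k > remaining:
            k = remaining
        sizes.append(k)
        remaining -= k
    if remaining == 1:
        if sizes:
            sizes[-1] += 1
        remaining = 0
    return sizes


def _cell_geometry(rng, params, is_myotube, n_nuclei):
    """Choose semi-axes and nucleus layout for one cell (before placement)."""
    r_nuc = params.nucleus_radius
    if not is_myotube:
        if params.eccentricity_sd == 0:
            e = params.eccentricity_mean
        else:
            e = rng.normal(params.eccentricity_mean, params.eccentricity_sd)
        e = float(np.clip(e, 0.0, 0.93))
        q = (1.0 - e * e) ** 0.25
        a = params.cell_radius / q
        b = params.cell_radius * q
        spacing = 0.0
    else:
        b = rng.uniform(max(r_nuc + 2.0, 7.0), max(r_nuc + 4.0, 9.0))
        # spread nuclei so the tube is at least 4x longer than wide
        spacing = max(2.0 * r_nuc + 4.0, 6.0 * b / max(n_nuclei - 1, 1))
        half_body = spacing * (n_nuclei - 1) / 2.0
        a = half_body + b
        e = math.sqrt(1.0 - (b / a) ** 2)
    return a, b, e, spacing


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Generate one field of view with ground truth.

    Raises :class:`PlacementError` when the requested cells cannot be
    placed without overlap within the rejection budget.
    """
    geo = np.random.default_rng([params.seed, 0])
    mark = np.random.default_rng([params.seed, 1])
    noise = np.random.default_rng([params.seed, 2])
    h, w = params.field_size

    # --- decide the cell roster ------------------------------------------
    if params.fusion_probability is not None:
        n_total = params.n_nuclei_total or params.n_cells
        fused = geo.random(n_total) < params.fusion_probability
        n_fused = int(fused.sum())
        if n_fused == 1:
            n_fused = 0
        weights = np.asarray(params.nuclei_count_weights, float)
        tube_sizes = _partition_fused(geo, n_fused, weights)
        n_mono = n_total - sum(tube_sizes)
        roster = [(True, k) for k in tube_sizes] + [(False, 1)] * n_mono
    else:
        weights = np.asarray(params.nuclei_count_weights, float)
        is_tube = geo.random(params.n_cells) < params.myotube_fraction
        tube_sizes = _draw_myotube_counts(geo, int(is_tube.sum()), weights)
        roster = [(True, k) for k in tube_sizes]
        roster += [(False, 1)] * int((~is_tube).sum())

    # --- geometry and placement (largest first) --------------------------
    geoms = [(_cell_geometry(geo, params, t, k), t, k) for t, k in roster]
    order = sorted(range(len(geoms)), key=lambda i: -geoms[i][0][0])
    placer = _Placer((h, w), params.min_separation)
    cells: list[TruthCell] = []
    for rank, i in enumerate(order):
        (a, b, e, spacing), is_tube, k = geoms[i]
        placed = placer.try_place(geo, max(a - b, 0.0), b)
        if placed is None:
            raise PlacementError(rank, len(geoms), _MAX_ATTEMPTS)
        centre, theta = placed
        u = _unit(theta)
        v = np.array([-u[1], u[0]])
        if is_tube:
            offs = (np.arange(k) - (k - 1) / 2.0) * spacing
            jitter = geo.uniform(-1.0, 1.0, size=k)
            nuclei = centre + offs[:, None] * u + jitter[:, None] * v
        else:
            jmax = max(min(2.0, b - params.nucleus_radius - 1.0), 0.0)
            r = jmax * math.sqrt(geo.random())
            phi = geo.uniform(0, 2 * math.pi)
            nuclei = (centre + r * np.array([math.sin(phi), math.cos(phi)]))[None, :]
        cells.append(
            TruthCell(
                cell_id=0, centre=tuple(centre), a=a, b=b, theta=theta,
                eccentricity=e, nuclei=nuclei, markers={}, is_myotube=is_tube,
            )
        )
    # stable ids in generation order
    for i, c in enumerate(cells, start=1):
        c.cell_id = i

    # --- marker states ----------------------------------------------------
    for name, p in params.marker_probs.items():
        draws = mark.random(len(cells)) < p
        for c, d in zip(cells, draws):
            c.markers[name] = bool(d) or (name == "myhc" and c.is_myotube)

    # --- rendering --------------------------------------------------------
    marker_names = list(params.marker_probs)
    chans = {"dapi": np.zeros((h, w)), "tubulin": np.zeros((h, w))}
    for m in marker_names:
        chans[m] = np.zeros((h, w))

    cyto_gain = 1.0 + 0.1 * noise.standard_normal(len(cells))
    nuc_gain = 1.0 + 0.05 * noise.standard_normal(len(cells))
    for c, cg, ng in zip(cells, cyto_gain, nuc_gain):
        mask, (r0, c0) = _render_cell_mask((h, w), c)
        level = _CYTO_LEVEL * max(cg, 0.5)
        sub = chans["tubulin"][r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
        np.maximum(sub, level * mask, out=sub)
        for m in marker_names:
            if c.markers.get(m, False):
                sub = chans[m][r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
                np.maximum(sub, level * mask, out=sub)
        for (nr, nc) in c.nuclei:
            _paint_disk(chans["dapi"], (nr, nc), params.nucleus_radius,
                        _NUC_LEVEL * max(ng, 0.5))

    if params.background_amplitude > 0:
        bg = _background_gradient((h, w), noise) * (
            params.background_amplitude * _CYTO_LEVEL
        )
        for ch in chans.values():
            ch += bg
    speckles: dict[str, np.ndarray] = {}
    if params.speckle_density > 0:
        for name, ch in chans.items():
            speckles[name] = _paint_speckles(ch, params.speckle_density, noise)
    if params.noise_sd > 0:
        for name in chans:
            chans[name] = chans[name] + noise.normal(0, params.noise_sd, (h, w))

    for name in chans:
        chans[name] = (np.clip(chans[name], 0.0, 1.0) * 65535).round().astype(np.uint16)

    frame = ImageFrame(
        channels=chans,
        metadata={
            "condition": params.condition, "dose": params.dose,
            "group": params.group, "frame_id": f"scene_{params.seed}",
            "seed": params.seed,
        },
    )
    return SyntheticScene(
        params=params, cells=cells, frame=frame,
        truth_table=_truth_table(cells, params), speckles=speckles,
    )


def _render_cell_mask(shape, cell: TruthCell):
    """Binary mask of one cell in a local window; returns (mask, origin)."""
    h, w = shape
    (cr, cc), a, b, th = cell.centre, cell.a, cell.b, cell.theta
    ext = a + 2.0
    r0, r1 = max(int(cr - ext), 0), min(int(cr + ext) + 2, h)
    c0, c1 = max(int(cc - ext), 0), min(int(cc + ext) + 2, w)
    rr, cc_ = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dr, dc = rr - cr, cc_ - cc
    u = _unit(th)
    x = dr * u[0] + dc * u[1]          # along major axis
    y = -dr * u[1] + dc * u[0]         # across
    if cell.is_myotube:
        half = a - b
        xc = np.clip(x, -half, half)
        mask = (x - xc) ** 2 + y**2 <= b * b
    else:
        mask = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    return mask.astype(float), (r0, c0)


def _paint_disk(img, centre, radius, level):
    h, w = img.shape
    cr, cc = centre
    r0, r1 = max(int(cr - radius) - 1, 0), min(int(cr + radius) + 2, h)
    c0, c1 = max(int(cc - radius) - 1, 0), min(int(cc + radius) + 2, w)
    rr, cc_ = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius * radius
    np.maximum(img[r0:r1, c0:c1], level * mask, out=img[r0:r1, c0:c1])


def _background_gradient(shape, rng):
    """Smooth 2-D cosine pattern in [0, 1], below one period per field."""
    h, w = shape
    fr, fc = rng.uniform(0.5, 1.0, 2)
    pr, pc = rng.uniform(0.0, 1.0, 2)
    r = np.arange(h)[:, None] / h
    c = np.arange(w)[None, :] / w
    return (0.5 * (1 + np.cos(2 * np.pi * (fr * r + pr)))
            * 0.5 * (1 + np.cos(2 * np.pi * (fc * c + pc))))


def _paint_speckles(img, density, rng):
    h, w = img.shape
    n = rng.poisson(density * h * w / 1e6)
    placed = np.empty((n, 3))
    for i in range(n):
        cr, cc = rng.uniform(0, h), rng.uniform(0, w)
        diam = rng.integers(3, 10)
        _paint_disk(img, (cr, cc), diam / 2.0, 1.0)
        placed[i] = (cr, cc, diam / 2.0)
    return placed


def _truth_table(cells, params) -> pd.DataFrame:
    marker_names = list(params.marker_probs)
    cols = {
        "cell_id": [c.cell_id for c in cells],
        "cx": [c.centre[1] for c in cells],
        "cy": [c.centre[0] for c in cells],
        "a": [c.a for c in cells],
        "b": [c.b for c in cells],
        "theta": [c.theta for c in cells],
        "eccentricity": [c.eccentricity for c in cells],
        "n_nuclei": [c.n_nuclei for c in cells],
        "is_myotube": [c.is_myotube for c in cells],
    }
    for m in marker_names:
        cols[f"marker_{m}"] = [bool(c.markers.get(m, False)) for c in cells]
    df = pd.DataFrame(cols)
    df["condition"] = params.condition
    df["dose"] = params.dose
    df["group"] = params.group
    return df


def write_scene(scene: SyntheticScene, outdir: str | Path) -> dict[str, Path]:
    """Write a scene as a multi-page TIFF plus sidecar truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = scene.frame.frame_id or "scene"
    tiff = write_frame(scene.frame, outdir / f"{stem}.tiff")
    csv = outdir / f"{stem}_truth.csv"
    scene.truth_table.to_csv(csv, index=False)
    return {"tiff": tiff, "truth": csv}


# ---------------------------------------------------------------------------
# outcome tables and count tables

@dataclass
class OutcomeTableSpec:
    """Data-generating process for per-cell Bernoulli outcomes.

    ``beta`` maps a factor name (or a tuple of names, for an
    interaction) to its log-odds coefficient.  The linear predictor for
    a cell is µ + Σ β·δ + c·dose + u_g with u_g ~ N(0, random_sd²)
    drawn once per group.
    """

    factors: list[str] = field(default_factory=list)
    mu: float = 0.0
    beta: dict = field(default_factory=dict)
    dose_coefficient: float | None = None
    doses: tuple[float, ...] = (0.0,)
    group_label: str = "mouse"
    n_groups: int = 1
    random_sd: float = 0.0
    cells_per_group_per_condition: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1:
            raise ValidationError("n_groups must be >= 1")
        if self.cells_per_group_per_condition < 1:
            raise ValidationError("cells_per_group_per_condition must be >= 1")
        if self.random_sd < 0:
            raise ValidationError("random_sd must be >= 0")
        for key in self.beta:
            names = key if isinstance(key, tuple) else (key,)
            for nm in names:
                if nm not in self.factors:
                    raise ValidationError(f"beta refers to unknown factor {nm!r}")


def generate_outcomes(spec: OutcomeTableSpec) -> pd.DataFrame:
    """Draw a tidy per-cell outcome table (one row per cell).

    Columns: one 0/1 column per factor, ``dose``, the group label
    column, and ``outcome``.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(0.0, spec.random_sd, spec.n_groups)
    combos = list(itertools.product([0, 1], repeat=len(spec.factors)))
    doses = spec.doses if spec.dose_coefficient is not None else (spec.doses[0],)
    blocks = []
    n = spec.cells_per_group_per_condition
    for g in range(spec.n_groups):
        for combo in combos:
            levels = dict(zip(spec.factors, combo))
            for dose in doses:
                eta = spec.mu + u[g]
                for key, b in spec.beta.items():
                    names = key if isinstance(key, tuple) else (key,)
                    eta += b * np.prod([levels[nm] for nm in names])
                if spec.dose_coefficient is not None:
                    eta += spec.dose_coefficient * dose
                if not np.isfinite(eta):
                    raise ValidationError(
                        f"non-finite linear predictor ({eta}) for levels {levels}"
                    )
                y = (rng.random(n) < expit(eta)).astype(int)
                block = {f: np.full(n, lev) for f, lev in levels.items()}
                block["dose"] = np.full(n, dose)
                block[spec.group_label] = np.full(n, f"{spec.group_label}_{g + 1}")
                block["outcome"] = y
                blocks.append(pd.DataFrame(block))
    return pd.concat(blocks, ignore_index=True)


def generate_counts(
    condition_means,
    dispersion: float = 1.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw replicate counts per condition with a given dispersion.

    ``dispersion`` = 1 draws Poisson; > 1 draws negative binomial
    parameterised so variance = dispersion × mean.  Returns a tidy
    table with columns ``condition``, ``replicate``, ``count``.
    """
    means = np.asarray(condition_means, dtype=float)
    if (means <= 0).any():
        raise ValidationError("condition means must be positive")
    if dispersion < 1:
        raise ValidationError("dispersion must be >= 1 (Poisson at exactly 1)")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i, m in enumerate(means):
        if dispersion == 1.0:
            counts = rng.poisson(m, n_replicates)
        else:
            r = m / (dispersion - 1.0)
            counts = rng.negative_binomial(r, 1.0 / dispersion, n_replicates)
        for j, c in enumerate(counts):
            rows.append(
                {"condition": f"cond_{i + 1}", "replicate": f"rep_{j + 1}",
                 "count": int(c)}
            )
    return pd.DataFrame(rows)
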