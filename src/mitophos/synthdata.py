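"""Synthetic phosphoproteomics tables and imaging data with exact ground truth.

Three generators cover the package's input kinds:

* ``simulate_phospho_table`` — log-normal phosphopeptide intensities with
  planted group effects on a chosen fraction of sites, multiplicative
  noise and a calibrated MCAR/MNAR missingness mixture.
* ``simulate_timelapse`` — capsule-shaped mitochondria rendered per frame
  with scripted fission/fusion at stated times, PSF blur and Gaussian
  noise; noiseless label masks are retained as ground truth.
* ``simulate_contact_geometry`` — mitochondria placed at controlled
  nanometre gaps from an ER ribbon for contact-site quantification.

All randomness flows through one ``numpy.random.Generator`` constructed
from the config seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .phospho import PhosphoPeptideTable
from .stack import LabeledStack

CONTACT_BAND_NM = (10.0, 30.0)


@dataclass
class GroundTruth:
    """Exact ground truth recorded by the generators.

    Only the fields relevant to the generator that produced it are
    populated; the rest keep their empty defaults.
    """

    true_significant_sites: set[str] = field(default_factory=set)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    true_delta_ps: dict[str, float] = field(default_factory=dict)
    true_particle_count_per_frame: list[int] = field(default_factory=list)
    true_event_log: list[dict[str, Any]] = field(default_factory=list)
    true_contact_flags: dict[int, bool] = field(default_factory=dict)
    true_distances_nm: dict[int, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "true_significant_sites": sorted(self.true_significant_sites),
            "true_log2fc": self.true_log2fc,
            "true_delta_ps": self.true_delta_ps,
            "true_particle_count_per_frame": self.true_particle_count_per_frame,
            "true_event_log": self.true_event_log,
            "true_contact_flags": {str(k): v for k, v in self.true_contact_flags.items()},
            "true_distances_nm": {str(k): v for k, v in self.true_distances_nm.items()},
        }


# ---------------------------------------------------------------------------
# phosphoproteomics
# ---------------------------------------------------------------------------


@dataclass
class PhosphoSimConfig:
    """Configuration of the phosphopeptide-table simulator.

    Intensities are log-normal: on the log2 scale each site draws a base
    level from N(base_mean, base_sd) and each observation adds Gaussian
    noise whose log2 sd corresponds to the multiplicative coefficient of
    variation ``cv``. Effects of magnitude ``effect_log2fc`` (random sign)
    are planted on ``effect_fraction`` of sites in every non-control group.
    Missingness is a calibrated mixture: a ``mnar_weight`` share of missing
    cells is drawn with probability decreasing logistically in intensity
    (missing-not-at-random), the remainder uniformly (completely at
    random).
    """

    n_proteins: int = 100
    peptides_per_protein: tuple[int, int] = (1, 4)
    n_groups: int = 2
    n_replicates: int = 4
    effect_fraction: float = 0.1
    effect_log2fc: float = 2.0
    cv: float = 0.2
    missing_rate: float = 0.1
    mnar_weight: float = 0.5
    base_mean: float = 25.0
    base_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("effect_fraction", "missing_rate", "mnar_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_proteins", "n_groups", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigurationError("peptides_per_protein must satisfy 1 <= min <= max")
        if self.cv < 0 or self.effect_log2fc < 0:
            raise ConfigurationError("cv and effect_log2fc must be non-negative")


def _noise_sd_log2(cv: float) -> float:
    """Log2-scale sd equivalent to a multiplicative coefficient of variation."""
    return float(np.sqrt(np.log(1.0 + cv**2)) / np.log(2.0)) if cv > 0 else 0.0


def simulate_phospho_table(config: PhosphoSimConfig) -> tuple[PhosphoPeptideTable, GroundTruth]:
    """Simulate a phosphopeptide × sample intensity table with ground truth.

    Groups are named ``control, group2, ..., groupG``; samples
    ``<group>_r<i>``. Planted effects shift the log2 mean of affected
    sites in every non-control group by ±``effect_log2fc``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=config.n_proteins)
    proteins = []
    site_ids = []
    for i, k in enumerate(n_pep):
        pid = f"P{i:04d}"
        for j in range(k):
            proteins.append(pid)
            site_ids.append(f"{pid}_S{j + 1}")
    n_sites = len(site_ids)

    groups = ["control"] + [f"group{g}" for g in range(2, config.n_groups + 1)]
    samples = [f"{g}_r{r + 1}" for g in groups for r in range(config.n_replicates)]
    design = {f"{g}_r{r + 1}": g for g in groups for r in range(config.n_replicates)}

    base = rng.normal(config.base_mean, config.base_sd, size=n_sites)
    n_effect = int(round(config.effect_fraction * n_sites))
    effect_idx = rng.choice(n_sites, size=n_effect, replace=False) if n_effect else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_effect)
    effect = np.zeros(n_sites)
    effect[effect_idx] = signs * config.effect_log2fc

    sd = _noise_sd_log2(config.cv)
    log2x = np.empty((n_sites, len(samples)))
    for j, s in enumerate(samples):
        mu = base if design[s] == "control" else base + effect
        log2x[:, j] = mu + rng.normal(0.0, sd, size=n_sites) if sd > 0 else mu
    intensities = np.power(2.0, log2x)

    # calibrated missingness: exact counts, MNAR share by intensity-weighted
    # sampling without replacement, MCAR share uniform over the rest
    n_cells = intensities.size
    n_missing = int(round(config.missing_rate * n_cells))
    mask = np.zeros(n_cells, dtype=bool)
    if n_missing:
        n_mnar = int(round(config.mnar_weight * n_missing))
        flat = log2x.ravel()
        if n_mnar:
            # logistic weight decreasing with log2 intensity, centred 1.5 sd
            # below the global mean with scale 0.5 sd
            scale = max(flat.std(), 1e-12)
            w = 1.0 / (1.0 + np.exp((flat - (flat.mean() - 1.5 * scale)) / (0.5 * scale)))
            w /= w.sum()
            mnar_idx = rng.choice(n_cells, size=n_mnar, replace=False, p=w)
            mask[mnar_idx] = True
        remaining = np.flatnonzero(~mask)
        n_mcar = n_missing - int(mask.sum())
        if n_mcar > 0:
            mcar_idx = rng.choice(remaining, size=n_mcar, replace=False)
            mask[mcar_idx] = True
    intensities = intensities.copy()
    intensities.ravel()[mask] = np.nan

    df = pd.DataFrame(intensities, index=pd.Index(site_ids, name="site_id"), columns=samples)
    table = PhosphoPeptideTable(
        intensities=df,
        proteins=pd.Series(proteins, index=df.index, name="protein_id"),
        design=design,
    )

    truth = GroundTruth()
    prot_series = pd.Series(proteins, index=site_ids)
    truth.true_significant_sites = {site_ids[i] for i in effect_idx}
    truth.true_log2fc = {site_ids[i]: float(effect[i]) for i in range(n_sites)}
    dps: dict[str, float] = {p: 0.0 for p in dict.fromkeys(proteins)}
    for i in effect_idx:
        dps[prot_series.iloc[i]] += float(effect[i])
    truth.true_delta_ps = dps
    return table, truth


# ---------------------------------------------------------------------------
# time-lapse dynamics
# ---------------------------------------------------------------------------


@dataclass
class DynamicsSimConfig:
    """Configuration of the capsule time-lapse simulator.

    Defaults emulate single-channel confocal time-lapse acquisition at one
    frame per 13 s over 10 min. ``fission_events`` is a list of
    ``(time_s, target_id)``; ``fusion_events`` a list of
    ``(time_s, (id_a, id_b))``. Initial objects receive ids ``1..n``;
    children of fissions and fusion products receive fresh ids.
    """

    field_size: tuple[int, int] = (192, 192)
    pixel_size: float = 0.1  # um / px
    frame_interval: float = 13.0  # s
    duration: float = 600.0  # s
    n_mitochondria: int = 5
    fission_events: list[tuple[float, int]] = field(default_factory=list)
    fusion_events: list[tuple[float, tuple[int, int]]] = field(default_factory=list)
    capsule_length: float = 20.0  # rod length, px
    capsule_radius: float = 3.0  # px
    drift_sd: float = 0.3  # px per frame random walk
    psf_sigma: float = 1.0  # px
    noise_sd: float = 2.0  # intensity units
    foreground: float = 100.0
    background: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.duration <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("frame_interval, duration and pixel_size must be positive")
        if self.n_mitochondria < 1:
            raise ConfigurationError("n_mitochondria must be >= 1")
        for t, _ in self.fission_events:
            if not 0 <= t <= self.duration:
                raise ConfigurationError(f"fission event time {t} outside [0, duration]")
        for t, _ in self.fusion_events:
            if not 0 <= t <= self.duration:
                raise ConfigurationError(f"fusion event time {t} outside [0, duration]")


@dataclass
class _Capsule:
    ident: int
    center: np.ndarray  # (row, col)
    angle: float  # radians
    length: float  # rod length, px
    radius: float  # px


def _render_capsule(mask: np.ndarray, cap: _Capsule, value: int) -> None:
    """Paint a capsule (rectangle with semicircular caps) into a label mask."""
    h, w = mask.shape
    d = np.array([np.cos(cap.angle), np.sin(cap.angle)])
    half = cap.length / 2.0
    a = cap.center - half * d
    b = cap.center + half * d
    r = cap.radius
    r0 = max(int(np.floor(min(a[0], b[0]) - r - 1)), 0)
    r1 = min(int(np.ceil(max(a[0], b[0]) + r + 1)) + 1, h)
    c0 = max(int(np.floor(min(a[1], b[1]) - r - 1)), 0)
    c1 = min(int(np.ceil(max(a[1], b[1]) + r + 1)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows, cols = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([rows, cols], axis=-1).astype(float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        dist = np.linalg.norm(pts - a, axis=-1)
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        dist = np.linalg.norm(pts - proj, axis=-1)
    mask[r0:r1, c0:c1][dist <= r] = value


def _capsule_extent(cap: _Capsule) -> float:
    return cap.length + 2 * cap.radius


def simulate_timelapse(config: DynamicsSimConfig) -> tuple[LabeledStack, GroundTruth]:
    """Render a scripted capsule time-lapse with ground-truth label masks.

    Fission splits a capsule at the midpoint of its axis into two shorter
    capsules separated by a 2 px gap; fusion replaces a pair with one
    capsule spanning both. Events scheduled at time ``t`` take effect at
    the first frame whose acquisition time is >= ``t``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.field_size
    n_frames = int(np.floor(config.duration / config.frame_interval)) + 1

    # place initial capsules on a jittered grid with margins
    caps: list[_Capsule] = []
    n = config.n_mitochondria
    grid = int(np.ceil(np.sqrt(n)))
    margin = config.capsule_length / 2 + config.capsule_radius + 4
    ys = np.linspace(margin, h - margin, grid)
    xs = np.linspace(margin, w - margin, grid)
    next_id = 1
    for i in range(n):
        gy, gx = divmod(i, grid)
        center = np.array([ys[gy], xs[gx]]) + rng.normal(0, 1.0, size=2)
        center = np.clip(center, margin, [h - margin, w - margin])
        angle = rng.uniform(0, np.pi)
        caps.append(_Capsule(next_id, center, angle, config.capsule_length, config.capsule_radius))
        next_id += 1

    events = sorted(
        [(t, "fission", tgt) for t, tgt in config.fission_events]
        + [(t, "fusion", pair) for t, pair in config.fusion_events],
        key=lambda e: e[0],
    )
    ev_i = 0

    frames = np.zeros((n_frames, h, w), dtype=np.float32)
    labels = np.zeros((n_frames, h, w), dtype=np.int32)
    truth = GroundTruth()

    gap = 2.0  # px between fission daughters
    for f in range(n_frames):
        t_frame = f * config.frame_interval
        while ev_i < len(events) and events[ev_i][0] <= t_frame:
            t_ev, kind, arg = events[ev_i]
            ev_i += 1
            by_id = {c.ident: c for c in caps}
            if kind == "fission":
                if arg not in by_id:
                    raise ConfigurationError(f"fission target id {arg} does not exist at t={t_ev}")
                parent = by_id[arg]
                d = np.array([np.cos(parent.angle), np.sin(parent.angle)])
                extent = _capsule_extent(parent)
                child_extent = (extent - gap) / 2.0
                child_rod = max(child_extent - 2 * parent.radius, 1.0)
                offset = (child_extent + gap) / 2.0
                c1 = _Capsule(next_id, parent.center - offset * d, parent.angle, child_rod, parent.radius)
                c2 = _Capsule(next_id + 1, parent.center + offset * d, parent.angle, child_rod, parent.radius)
                next_id += 2
                caps = [c for c in caps if c.ident != parent.ident] + [c1, c2]
                truth.true_event_log.append(
                    {"type": "fission", "time": float(t_ev), "frame": f,
                     "parents": [parent.ident], "children": [c1.ident, c2.ident]}
                )
            else:
                ia, ib = arg
                if ia not in by_id or ib not in by_id:
                    raise ConfigurationError(f"fusion pair {arg} does not exist at t={t_ev}")
                a, b = by_id[ia], by_id[ib]
                axis = b.center - a.center
                dist = float(np.linalg.norm(axis))
                angle = float(np.arctan2(axis[1], axis[0])) if dist > 0 else a.angle
                rod = dist + (a.length + b.length) / 2.0
                merged = _Capsule(next_id, (a.center + b.center) / 2.0, angle, rod,
                                  max(a.radius, b.radius))
                next_id += 1
                caps = [c for c in caps if c.ident not in (ia, ib)] + [merged]
                truth.true_event_log.append(
                    {"type": "fusion", "time": float(t_ev), "frame": f,
                     "parents": [ia, ib], "children": [merged.ident]}
                )
        # random walk drift; centres clamped so objects stay clear of the
        # field border (edge-touching objects would mimic events)
        if config.drift_sd > 0 and f > 0:
            for c in caps:
                c.center = c.center + rng.normal(0, config.drift_sd, size=2)
                m = min(_capsule_extent(c) / 2.0 + 4.0, min(h, w) / 2.0 - 1.0)
                c.center = np.clip(c.center, m, [h - m, w - m])

        lab = np.zeros((h, w), dtype=np.int32)
        for c in sorted(caps, key=lambda c: c.ident):
            _render_capsule(lab, c, c.ident)
        labels[f] = lab
        img = np.where(lab > 0, config.foreground, config.background).astype(np.float32)
        if config.psf_sigma > 0:
            img = gaussian_filter(img, config.psf_sigma)
        if config.noise_sd > 0:
            img = img + rng.normal(0, config.noise_sd, size=img.shape).astype(np.float32)
        frames[f] = np.clip(img, 0, None)
        truth.true_particle_count_per_frame.append(len(caps))

    stack = LabeledStack(frames=frames, pixel_size=config.pixel_size,
                         frame_interval=config.frame_interval, labels=labels)
    return stack, truth


# ---------------------------------------------------------------------------
# ER-mitochondria contact geometry
# ---------------------------------------------------------------------------


def simulate_contact_geometry(
    distances_nm: list[float],
    pixel_size_nm: float = 2.5,
    band: tuple[float, float] = CONTACT_BAND_NM,
    mito_radius_nm: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Place one mitochondrion per requested gap distance from an ER ribbon.

    The ER is a vertical ribbon on the left of the field; mitochondrion
    ``i`` (label ``i + 1``) is a disk whose minimum edge-to-edge gap to the
    ER equals ``distances_nm[i]``. The edge-to-edge convention counts the
    empty space between boundary pixels: two touching pixels have gap 0.
    True contact flags apply the inclusive ``band`` rule to the *requested*
    distances.

    Returns ``(mito_labels, er_mask, truth)`` where ``mito_labels`` is an
    integer label image and ``er_mask`` a boolean mask.

    Raises
    ------
    ConfigurationError
        If a distance is negative or rounds to a gap below one pixel
        (unresolvable at this pixel size; sampling at <= 5 nm/px is
        recommended for the 10-30 nm band).
    """
    if pixel_size_nm <= 0:
        raise ConfigurationError("pixel_size_nm must be positive")
    if not distances_nm:
        raise ConfigurationError("at least one distance is required")
    gaps_px = []
    for d in distances_nm:
        if d < 0:
            raise ConfigurationError(f"distance must be >= 0, got {d}")
        g = int(round(d / pixel_size_nm))
        if d > 0 and g < 1:
            raise ConfigurationError(
                f"distance {d} nm is unresolvable at {pixel_size_nm} nm/px"
            )
        gaps_px.append(g)

    r_px = max(int(round(mito_radius_nm / pixel_size_nm)), 2)
    row_height = 2 * r_px + 8
    h = row_height * len(distances_nm) + 8
    er_right = 8  # ER ribbon occupies columns [2, er_right]
    w = er_right + 1 + max(gaps_px) + 2 * r_px + 12

    er = np.zeros((h, w), dtype=bool)
    er[2:-2, 2:er_right + 1] = True
    mito = np.zeros((h, w), dtype=np.int32)
    rows, cols = np.mgrid[0:h, 0:w]
    truth = GroundTruth()
    for i, (d, g) in enumerate(zip(distances_nm, gaps_px)):
        cy = 4 + row_height * i + r_px
        # leftmost mito pixel sits g empty columns right of the ER edge
        cx = er_right + 1 + g + r_px
        disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= r_px**2
        mito[disk] = i + 1
        truth.true_contact_flags[i] = bool(band[0] <= d <= band[1])
        truth.true_distances_nm[i] = float(d)
    return mito, er, truth
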