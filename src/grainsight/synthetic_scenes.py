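"""Synthetic multispectral grain scenes with exact ground truth.

Emulates a backlit five-channel (R, G, B, NIR1, NIR2) acquisition of rice
grains spread on a translucent stage: dark elongated grains on a bright
background, partial adhesion between touching grains, salt-noise specks and
small impurity blobs, and three defect phenotypes (lesion spots, mildew
patches, immature grains).  Every scene comes with per-grain instance masks,
class labels and adhesion-cluster bookkeeping, so the generator doubles as
the oracle for segmentation and classification experiments.

Photometric conventions
-----------------------
* Backlit stage: every grain pixel is darker than the background in every
  channel (before noise injection).
* Grains are rendered as rotated ellipses with a radial shading profile —
  a flat translucent core brightening steeply toward the rim — which is what
  gives the gradient-watershed a ridge to find.
* Where two grains touch, the contact line occludes the backlight (a dark
  seam), flanked by narrow bright crevice wedges where light leaks between
  the curved bodies; everything stays below the binarization threshold, so
  the pair remains a single connected component in the mask.
* NIR planes are the luminance rendering passed through a wider smoothing
  kernel with lower additive noise, and defects have reduced (but nonzero)
  NIR contrast: longer wavelengths scatter less and see a smoother surface.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

CHANNEL_NAMES: tuple[str, ...] = ("R", "G", "B", "NIR1", "NIR2")

#: luminance weights used for the NIR base rendering and for gray conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

DEFECT_KINDS = ("lesion", "mildew", "immature")


class PlacementError(RuntimeError):
    """Raised when a scene is too crowded to place the requested grains."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placement failure: placed {placed} of {requested} grains "
            f"before exhausting the retry cap"
        )


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Geometric parameters are in pixels; photometric levels are 8-bit
    intensities.  ``defect_mix`` orders probabilities as
    (lesion, mildew, immature) and must sum to 1.
    """

    width: int = 768
    height: int = 768
    n_grains: int = 100
    adhesion_prob: float = 0.2
    imperfect_frac: float = 0.3
    defect_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    grain_length_px: tuple[float, float] = (56.0, 3.5)
    aspect_ratio: tuple[float, float] = (2.8, 0.2)
    noise_rate: float = 2.0  # expected salt/pepper specks per 1e4 bg pixels
    impurity_count: int = 3
    seed: int = 0

    # --- photometry (8-bit levels; backlit: grains darker than background) ---
    background_level: float = 230.0
    core_rgb: tuple[float, float, float] = (150.0, 143.0, 128.0)
    rim_level: float = 172.0
    shading_power: float = 6.0
    seam_level: float = 188.0
    seam_width_px: float = 1.0
    contact_dark_level: float = 90.0
    sensor_noise_rgb: float = 4.0
    sensor_noise_nir: float = 1.5
    rgb_blur_sigma: float = 0.5
    nir_blur_sigma: float = 1.4
    nir2_blur_sigma: float = 1.8
    nir2_gain: float = 0.97

    # --- defect rendering ---
    lesion_contrast_rgb: float = 70.0
    lesion_contrast_nir: float = 25.0
    mildew_contrast_rgb: float = 45.0
    mildew_contrast_nir: float = 18.0
    immature_brighten: float = 35.0
    immature_shrink: tuple[float, float] = (0.75, 0.90)

    max_cluster_size: int = 4

    def validate(self) -> None:
        if self.n_grains < 0:
            raise ValueError("n_grains must be >= 0")
        for name in ("adhesion_prob", "imperfect_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if any(p < 0 for p in self.defect_mix) or abs(sum(self.defect_mix) - 1.0) > 1e-9:
            raise ValueError("defect_mix must be nonnegative and sum to 1")
        if self.grain_length_px[0] <= 0:
            raise ValueError("mean grain length must be > 0")
        if self.aspect_ratio[0] <= 1:
            raise ValueError("mean aspect ratio must be > 1")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")

    @property
    def expected_grain_area(self) -> float:
        """Mean single-grain area in px (ellipse with the spec's mean axes)."""
        a = self.grain_length_px[0] / 2.0
        b = a / self.aspect_ratio[0]
        return math.pi * a * b


@dataclass
class GrainParams:
    """Rendered ellipse of one grain: center (row, col), semi-axes, angle."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (major, minor)
    orientation: float  # radians, of the major axis, in (row, col) frame


@dataclass
class SceneGroundTruth:
    """Exact per-grain truth for one generated scene."""

    instance_mask: np.ndarray  # H x W int32; 0 = background, k = grain k
    labels: list[str]  # 'perfect' | 'imperfect', per grain (index k-1)
    defect_types: list[Optional[str]]  # defect kind for imperfect grains
    cluster_ids: list[int]  # adhesion-cluster id per grain
    grain_params: list[GrainParams]

    @property
    def n_grains(self) -> int:
        return len(self.labels)

    def grain_mask(self, k: int) -> np.ndarray:
        """Boolean mask of grain ``k`` (1-based label)."""
        return self.instance_mask == k


@dataclass
class MultiChannelImage:
    """Five co-registered 8-bit planes in fixed (R, G, B, NIR1, NIR2) order.

    ``planes`` is an (H, W, 5) uint8 array; channel-last everywhere in the
    package.
    """

    planes: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or self.planes.shape[2] != len(self.channel_names):
            raise ValueError(
                f"planes must be (H, W, {len(self.channel_names)}), "
                f"got {self.planes.shape}"
            )
        if self.planes.dtype != np.uint8:
            raise ValueError("planes must be uint8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[:2]

    def plane(self, name: str) -> np.ndarray:
        return self.planes[..., self.channel_names.index(name)]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _support_radius(a: float, b: float, theta: float, direction: float) -> float:
    """Radius of an ellipse boundary along an absolute direction angle."""
    psi = direction - theta
    return (a * b) / math.hypot(b * math.cos(psi), a * math.sin(psi))


def _norm_dist_patch(
    shape: tuple[int, int], g: GrainParams, pad: float
) -> tuple[slice, slice, np.ndarray]:
    """Normalized elliptic distance of ``g`` over its padded bounding patch.

    Returns (row slice, col slice, d) where d <= 1 inside the ellipse.
    """
    (cr, cc), (a, b), th = g.center, g.semi_axes, g.orientation
    r = a + pad + 1.0
    r0 = max(int(math.floor(cr - r)), 0)
    r1 = min(int(math.ceil(cr + r)) + 1, shape[0])
    c0 = max(int(math.floor(cc - r)), 0)
    c1 = min(int(math.ceil(cc + r)) + 1, shape[1])
    rows = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    cols = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    # rotate into the ellipse frame; orientation measured in (row, col)
    u = rows * math.cos(th) + cols * math.sin(th)
    v = -rows * math.sin(th) + cols * math.cos(th)
    d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return slice(r0, r1), slice(c0, c1), d


@dataclass
class _Grain:
    params: GrainParams
    label: str
    defect: Optional[str]
    cluster: int


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

_FREE_ATTEMPTS = 150
_ADHESION_ATTEMPTS = 80
_CLEARANCE_PX = 2.0


def _sample_shape(spec: SceneSpec, rng: np.random.Generator) -> tuple[float, float, float, str, Optional[str]]:
    """Draw (a, b, theta, label, defect) for one grain."""
    mean_l, sd_l = spec.grain_length_px
    length = float(np.clip(rng.normal(mean_l, sd_l), 0.55 * mean_l, 1.45 * mean_l))
    mean_ar, sd_ar = spec.aspect_ratio
    aspect = float(np.clip(rng.normal(mean_ar, sd_ar), 1.2, mean_ar + 4 * sd_ar + 0.5))
    label = "imperfect" if rng.random() < spec.imperfect_frac else "perfect"
    defect = None
    if label == "imperfect":
        defect = DEFECT_KINDS[int(rng.choice(3, p=np.asarray(spec.defect_mix)))]
    a = length / 2.0
    b = a / aspect
    if defect == "immature":
        lo, hi = spec.immature_shrink
        s = float(rng.uniform(lo, hi))
        a *= s
        b *= s
    theta = float(rng.uniform(0.0, math.pi))
    return a, b, theta, label, defect


def _place_grains(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[list[_Grain], list[tuple[int, int]]]:
    """Rejection-sample grain positions; returns grains and contact pairs."""
    shape = (spec.height, spec.width)
    occ = np.zeros(shape, dtype=np.int32)  # cluster id of occupied px (+clearance)
    grains: list[_Grain] = []
    contacts: list[tuple[int, int]] = []
    cluster_sizes: dict[int, int] = {}
    next_cluster = 1

    for k in range(spec.n_grains):
        a, b, theta, label, defect = _sample_shape(spec, rng)
        margin = a + 3.0
        placed = False

        partners = [
            i for i, g in enumerate(grains)
            if cluster_sizes[g.cluster] < spec.max_cluster_size
        ]
        try_adhere = bool(partners) and rng.random() < spec.adhesion_prob

        if try_adhere:
            pi = partners[int(rng.integers(len(partners)))]
            pg = grains[pi]
            for _ in range(_ADHESION_ATTEMPTS):
                direction = float(rng.uniform(0.0, 2 * math.pi))
                r1 = _support_radius(*pg.params.semi_axes, pg.params.orientation, direction)
                r2 = _support_radius(a, b, theta, direction + math.pi)
                # contact depth: 5-30% of the smaller grain's minor axis
                depth = float(rng.uniform(0.05, 0.30)) * 2.0 * min(pg.params.semi_axes[1], b)
                d = r1 + r2 - depth
                cr = pg.params.center[0] + d * math.cos(direction)
                cc = pg.params.center[1] + d * math.sin(direction)
                if not (margin <= cr <= shape[0] - margin and margin <= cc <= shape[1] - margin):
                    continue
                cand = GrainParams((cr, cc), (a, b), theta)
                rs, cs, dd = _norm_dist_patch(shape, cand, _CLEARANCE_PX)
                inside = dd <= 1.0 + _CLEARANCE_PX / b
                hit = occ[rs, cs][inside]
                if not np.all((hit == 0) | (hit == pg.cluster)):
                    continue
                # the candidate may also touch other members of the target
                # cluster: every genuine contact needs a rendered seam, and
                # no secondary contact may bury deeper than ~35% minor axis
                touching = []
                too_deep = False
                for mi, mg in enumerate(grains):
                    if mg.cluster != pg.cluster:
                        continue
                    mc = mg.params.center
                    dist = math.hypot(cr - mc[0], cc - mc[1])
                    direction_m = math.atan2(cc - mc[1], cr - mc[0])
                    rm = _support_radius(*mg.params.semi_axes, mg.params.orientation, direction_m)
                    rn = _support_radius(a, b, theta, direction_m + math.pi)
                    pen = rm + rn - dist
                    if pen > 0.35 * 2.0 * min(mg.params.semi_axes[1], b):
                        too_deep = True
                        break
                    if pen > -1.5:  # overlapping or blur-bridged
                        touching.append(mi)
                if too_deep or pi not in touching:
                    continue
                cl = pg.cluster
                grains.append(_Grain(cand, label, defect, cl))
                contacts.extend((mi, k) for mi in touching)
                cluster_sizes[cl] += 1
                occ[rs, cs][...] = np.where(inside, cl, occ[rs, cs])
                placed = True
                break

        if not placed:
            for _ in range(_FREE_ATTEMPTS):
                cr = float(rng.uniform(margin, shape[0] - margin))
                cc = float(rng.uniform(margin, shape[1] - margin))
                cand = GrainParams((cr, cc), (a, b), theta)
                rs, cs, dd = _norm_dist_patch(shape, cand, _CLEARANCE_PX)
                inside = dd <= 1.0 + _CLEARANCE_PX / b
                if not occ[rs, cs][inside].any():
                    cl = next_cluster
                    next_cluster += 1
                    grains.append(_Grain(cand, label, defect, cl))
                    cluster_sizes[cl] = 1
                    occ[rs, cs][...] = np.where(inside, cl, occ[rs, cs])
                    placed = True
                    break

        if not placed:
            raise PlacementError(len(grains), spec.n_grains)

    return grains, contacts


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_instances(
    shape: tuple[int, int], grains: Sequence[_Grain]
) -> tuple[np.ndarray, np.ndarray]:
    """Instance mask by nearest normalized elliptic distance.

    Overlap pixels of adhered grains go to the grain whose normalized
    distance is smaller, which keeps per-grain masks disjoint.
    """
    inst = np.zeros(shape, dtype=np.int32)
    dist = np.full(shape, np.inf, dtype=np.float64)
    for k, g in enumerate(grains, start=1):
        rs, cs, d = _norm_dist_patch(shape, g.params, 0.0)
        sub_d = dist[rs, cs]
        sub_i = inst[rs, cs]
        closer = (d <= 1.0) & (d < sub_d)
        sub_d[closer] = d[closer]
        sub_i[closer] = k
        dist[rs, cs] = sub_d
        inst[rs, cs] = sub_i
    _enforce_connectivity(inst, grains)
    return inst, dist


def _enforce_connectivity(inst: np.ndarray, grains: Sequence[_Grain]) -> None:
    """Reassign ownership slivers so every grain stays 4-connected.

    Nearest-ellipse ownership can cut off a few pixels near the tips of an
    overlap lens; such minor components are handed to the most common
    4-neighboring grain (or dropped to background if isolated).
    """
    from scipy import ndimage as _ndi

    for _ in range(5):
        changed = False
        for k, g in enumerate(grains, start=1):
            rs, cs, _d = _norm_dist_patch(inst.shape, g.params, 1.0)
            sub = inst[rs, cs]
            m = sub == k
            lab, n = _ndi.label(m)
            if n <= 1:
                continue
            changed = True
            sizes = np.bincount(lab.ravel())
            keep = int(np.argmax(sizes[1:])) + 1
            for ci in range(1, n + 1):
                if ci == keep:
                    continue
                comp = lab == ci
                ring = _ndi.binary_dilation(comp) & ~comp
                neigh = sub[ring]
                neigh = neigh[(neigh != k) & (neigh != 0)]
                sub[comp] = np.bincount(neigh).argmax() if neigh.size else 0
        if not changed:
            break


def _render_clean(
    spec: SceneSpec, grains: Sequence[_Grain], contacts: Sequence[tuple[int, int]],
    inst: np.ndarray,
) -> np.ndarray:
    """Noise-free float planes (H, W, 4): R, G, B and the NIR base rendering."""
    shape = (spec.height, spec.width)
    bg = spec.background_level
    planes = np.full(shape + (4,), bg, dtype=np.float64)
    core_nir = float(np.dot(LUMA_WEIGHTS, spec.core_rgb))
    rng_local = np.random.default_rng(spec.seed + 7_777_777)  # defect geometry

    for k, g in enumerate(grains, start=1):
        rs, cs, d = _norm_dist_patch(shape, g.params, 0.0)
        owned = inst[rs, cs] == k
        if not owned.any():
            continue
        rho = np.clip(d, 0.0, 1.0)
        shade = rho ** spec.shading_power
        cores = list(spec.core_rgb) + [core_nir]
        if g.defect == "immature":
            cores = [c + spec.immature_brighten for c in cores]

        # per-channel darkening field from lesion / mildew, scaled later
        defect_w = np.zeros_like(d)
        if g.defect == "lesion":
            n_spots = int(rng_local.integers(1, 4))
            a, b = g.params.semi_axes
            for _ in range(n_spots):
                # spot center inside the grain, in the ellipse frame
                rad = float(rng_local.uniform(0.0, 0.55))
                ang = float(rng_local.uniform(0.0, 2 * math.pi))
                th = g.params.orientation
                dr = rad * (a * math.cos(ang) * math.cos(th) - b * math.sin(ang) * math.sin(th))
                dc = rad * (a * math.cos(ang) * math.sin(th) + b * math.sin(ang) * math.cos(th))
                scr = g.params.center[0] + dr - rs.start
                scc = g.params.center[1] + dc - cs.start
                srad = float(rng_local.uniform(2.0, 4.0))
                rr = np.arange(d.shape[0], dtype=np.float64)[:, None] - scr
                cc2 = np.arange(d.shape[1], dtype=np.float64)[None, :] - scc
                rr2 = (rr ** 2 + cc2 ** 2) / srad ** 2
                defect_w = np.maximum(defect_w, np.clip(1.0 - rr2, 0.0, 1.0))
        elif g.defect == "mildew":
            frac = float(rng_local.uniform(0.2, 0.6))
            s = math.sqrt(frac)
            off_rad = float(rng_local.uniform(0.0, 0.35))
            off_ang = float(rng_local.uniform(0.0, 2 * math.pi))
            a, b = g.params.semi_axes
            th = g.params.orientation
            dr = off_rad * (a * math.cos(off_ang) * math.cos(th) - b * math.sin(off_ang) * math.sin(th))
            dc = off_rad * (a * math.cos(off_ang) * math.sin(th) + b * math.sin(off_ang) * math.cos(th))
            patch = GrainParams(
                (g.params.center[0] + dr, g.params.center[1] + dc),
                (s * a, s * b), th,
            )
            prs, pcs, pd = _norm_dist_patch(shape, patch, 0.0)
            w_full = np.zeros(shape, dtype=np.float64)
            w_full[prs, pcs] = np.clip(1.0 - pd ** 2, 0.0, 1.0)
            defect_w = w_full[rs, cs]

        contrasts = {
            "lesion": (spec.lesion_contrast_rgb, spec.lesion_contrast_nir),
            "mildew": (spec.mildew_contrast_rgb, spec.mildew_contrast_nir),
        }
        for ch in range(4):
            val = cores[ch] + (spec.rim_level - cores[ch]) * shade
            if g.defect in contrasts:
                c_rgb, c_nir = contrasts[g.defect]
                val = val - (c_nir if ch == 3 else c_rgb) * defect_w
            sub = planes[rs, cs, ch]
            sub[owned] = np.minimum(val, bg - 5.0)[owned]
            planes[rs, cs, ch] = sub

    # contact seams: a dark occlusion line where the grains press together,
    # flanked by bright crevice wedges where the backlight leaks through
    for i, j in contacts:
        gi, gj = grains[i], grains[j]
        rsi, csi, di = _norm_dist_patch(shape, gi.params, 1.0)
        rsj, csj, dj = _norm_dist_patch(shape, gj.params, 1.0)
        r0 = max(rsi.start, rsj.start); r1 = min(rsi.stop, rsj.stop)
        c0 = max(csi.start, csj.start); c1 = min(csi.stop, csj.stop)
        if r0 >= r1 or c0 >= c1:
            continue
        di_o = di[r0 - rsi.start:r1 - rsi.start, c0 - csi.start:c1 - csi.start]
        dj_o = dj[r0 - rsj.start:r1 - rsj.start, c0 - csj.start:c1 - csj.start]
        # near-contact wedge: the crevice extends a couple of px beyond the
        # exact overlap lens (where the blurred silhouettes still bridge)
        bi = gi.params.semi_axes[1]
        bj = gj.params.semi_axes[1]
        overlap = (di_o <= 1.0 + 3.5 / bi) & (dj_o <= 1.0 + 3.5 / bj)
        if not overlap.any():
            continue
        # signed pixel distance to the contact line (first-order), so the
        # seam has the same physical width whatever the contact orientation
        diff = di_o - dj_o
        gr, gc = np.gradient(diff)
        slope = np.maximum(np.hypot(gr, gc), 1e-6)
        s_px = diff / slope
        sw = max(spec.seam_width_px, 1e-6)
        # dark occlusion line at the contact, bright crevice wedges beside it
        w_bright = np.exp(-0.5 * ((np.abs(s_px) - 2.2 * sw) / sw) ** 2) * overlap
        w_dark = np.exp(-0.5 * (s_px / (0.8 * sw)) ** 2) * overlap
        sub = planes[r0:r1, c0:c1, :]
        bright_target = min(spec.seam_level, bg - 5.0)
        lift = (bright_target - sub) * w_bright[..., None]
        sub = sub + np.maximum(lift, 0.0)
        drop = (spec.contact_dark_level - sub) * w_dark[..., None]
        sub = sub + np.minimum(drop, 0.0)
        planes[r0:r1, c0:c1, :] = sub

    return planes


def _add_impurities(
    spec: SceneSpec, planes: np.ndarray, inst: np.ndarray, rng: np.random.Generator
) -> None:
    """Small dark debris blobs on the background, away from grains."""
    shape = inst.shape
    for _ in range(spec.impurity_count):
        for _ in range(100):
            cr = float(rng.uniform(8, shape[0] - 8))
            cc = float(rng.uniform(8, shape[1] - 8))
            a = float(rng.uniform(1.5, 3.2))
            b = a * float(rng.uniform(0.5, 1.0))
            th = float(rng.uniform(0.0, math.pi))
            g = GrainParams((cr, cc), (a, b), th)
            rs, cs, d = _norm_dist_patch(shape, g, 4.0)
            near = d <= 1.0 + 4.0 / b
            if inst[rs, cs][near].any():
                continue
            inside = d <= 1.0
            level = float(rng.uniform(100.0, 150.0))
            sub = planes[rs, cs, :]
            sub[inside] = level
            planes[rs, cs, :] = sub
            break


def _finalize_planes(
    spec: SceneSpec, clean: np.ndarray, inst: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Optical blur, channel derivation, sensor noise, specks, quantization."""
    out = np.empty(clean.shape[:2] + (5,), dtype=np.float64)
    for ch in range(3):
        out[..., ch] = gaussian_filter(clean[..., ch], spec.rgb_blur_sigma, mode="reflect")
    nir_base = clean[..., 3]
    out[..., 3] = gaussian_filter(nir_base, spec.nir_blur_sigma, mode="reflect")
    out[..., 4] = gaussian_filter(nir_base, spec.nir2_blur_sigma, mode="reflect") * spec.nir2_gain

    for ch in range(5):
        sd = spec.sensor_noise_rgb if ch < 3 else spec.sensor_noise_nir
        if sd > 0:
            out[..., ch] += rng.normal(0.0, sd, size=out.shape[:2])

    # salt/pepper specks on the background (dust on the stage; all channels)
    bg_idx = np.flatnonzero(inst.ravel() == 0)
    if bg_idx.size and spec.noise_rate > 0:
        n_specks = rng.binomial(bg_idx.size, min(spec.noise_rate / 1e4, 1.0))
        if n_specks:
            chosen = rng.choice(bg_idx, size=n_specks, replace=False)
            vals = np.where(rng.random(n_specks) < 0.5, 0.0, 255.0)
            rr, cc = np.unravel_index(chosen, inst.shape)
            out[rr, cc, :] = vals[:, None]

    return np.floor(np.clip(out, 0.0, 255.0) + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec) -> tuple[MultiChannelImage, SceneGroundTruth]:
    """Render one scene; deterministic for a given ``spec`` (seed included).

    Raises
    ------
    PlacementError
        If the scene is too crowded to place ``spec.n_grains`` grains.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grains, contacts = _place_grains(spec, rng)
    inst, _ = _paint_instances((spec.height, spec.width), grains)
    clean = _render_clean(spec, grains, contacts, inst)
    _add_impurities(spec, clean, inst, rng)
    planes = _finalize_planes(spec, clean, inst, rng)
    gt = SceneGroundTruth(
        instance_mask=inst,
        labels=[g.label for g in grains],
        defect_types=[g.defect for g in grains],
        cluster_ids=[g.cluster for g in grains],
        grain_params=[g.params for g in grains],
    )
    return MultiChannelImage(planes), gt


def render_clean_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Noise-free float planes (H, W, 5) before sensor noise and specks.

    Used to verify photometric contracts (grain pixels below background in
    every channel) that would otherwise be blurred by noise injection.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grains, contacts = _place_grains(spec, rng)
    inst, _ = _paint_instances((spec.height, spec.width), grains)
    clean = _render_clean(spec, grains, contacts, inst)
    out = np.empty(clean.shape[:2] + (5,), dtype=np.float64)
    for ch in range(3):
        out[..., ch] = gaussian_filter(clean[..., ch], spec.rgb_blur_sigma, mode="reflect")
    out[..., 3] = gaussian_filter(clean[..., 3], spec.nir_blur_sigma, mode="reflect")
    out[..., 4] = gaussian_filter(clean[..., 3], spec.nir2_blur_sigma, mode="reflect") * spec.nir2_gain
    gt = SceneGroundTruth(
        instance_mask=inst,
        labels=[g.label for g in grains],
        defect_types=[g.defect for g in grains],
        cluster_ids=[g.cluster for g in grains],
        grain_params=[g.params for g in grains],
    )
    return out, gt


def scene_seed(base_seed: int, index: int) -> int:
    """Per-scene seed scheme: ``base_seed + index`` (kept below 2**31)."""
    return int((base_seed + index) % (2 ** 31))


def generate_dataset(n_scenes: int, spec: SceneSpec, out_dir: str | Path) -> dict:
    """Write ``n_scenes`` scenes (channel PNGs, 16-bit mask PNG, label JSON).

    Returns the manifest (also written to ``out_dir/manifest.json``).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out}: {e}") from e

    manifest: dict = {"n_scenes": n_scenes, "base_seed": spec.seed, "scenes": []}
    for i in range(n_scenes):
        sspec = replace(spec, seed=scene_seed(spec.seed, i))
        image, gt = generate_scene(sspec)
        name = f"scene_{i:03d}"
        files = {}
        for ch, cname in enumerate(CHANNEL_NAMES):
            path = out / f"{name}_{cname}.png"
            iio.imwrite(path, image.planes[..., ch])
            files[cname] = path.name
        mask_path = out / f"{name}_mask.png"
        if gt.instance_mask.max() > np.iinfo(np.uint16).max:
            raise ValueError("too many grains for a 16-bit instance mask")
        iio.imwrite(mask_path, gt.instance_mask.astype(np.uint16))
        labels_path = out / f"{name}_labels.json"
        labels_path.write_text(json.dumps({
            "labels": gt.labels,
            "defect_types": gt.defect_types,
            "cluster_ids": gt.cluster_ids,
            "grain_params": [
                {
                    "center": list(p.center),
                    "semi_axes": list(p.semi_axes),
                    "orientation": p.orientation,
                }
                for p in gt.grain_params
            ],
        }, indent=1))
        manifest["scenes"].append({
            "name": name,
            "seed": sspec.seed,
            "channels": files,
            "mask": mask_path.name,
            "labels": labels_path.name,
            "n_grains": gt.n_grains,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_scene(out_dir: str | Path, entry: dict) -> tuple[MultiChannelImage, SceneGroundTruth]:
    """Load one scene previously written by :func:`generate_dataset`."""
    out = Path(out_dir)
    planes = np.stack(
        [iio.imread(out / entry["channels"][c]) for c in CHANNEL_NAMES], axis=-1
    ).astype(np.uint8)
    inst = iio.imread(out / entry["mask"]).astype(np.int32)
    meta = json.loads((out / entry["labels"]).read_text())
    gt = SceneGroundTruth(
        instance_mask=inst,
        labels=meta["labels"],
        defect_types=meta["defect_types"],
        cluster_ids=meta["cluster_ids"],
        grain_params=[
            GrainParams(tuple(p["center"]), tuple(p["semi_axes"]), p["orientation"])
            for p in meta["grain_params"]
        ],
    )
    return MultiChannelImage(planes), gt
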