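"""Parametric generator of ground-truthed carrot silhouettes.

A carrot is modelled in its own frame as a tapered band around a bent
midline: columns x in [0, L) carry a width profile

    w(x) = base_width * ((1 - t) * (1 - tip) + tip) ** taper,   t = x / L

(``tip`` keeps the thin end a few pixels wide so it rasterises), and a
quadratic-arc midline

    f(x) = curvature * L * 4 t (1 - t)

whose peak offset is ``curvature * L`` — curvature is therefore the
midline arc offset as a fraction of length.  Irregular morphologies are
composed on top: forked roots duplicate the distal midline with
diverging perpendicular offsets (2 or 3 thinner branches past a branch
point), broken roots are truncated with a flat cut.  The whole
silhouette can then be rotated and rendered as an RGB photograph stand-
in (dark-blue-channel carrot on a bright background with Gaussian pixel
noise) for end-to-end pipeline tests.

Every rendered sample carries its analytic ground truth — midline, width
profile, true class and true root count — so feature extractors can be
checked against closed-form values instead of against themselves.

The default morphometry lives in ``data/generator_defaults.yaml``; a
dataset drawn from those ranges (56 regular + 79 irregular, seed 2020)
is the package's standard fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError, InvalidSpecError

__all__ = [
    "SilhouetteSpec",
    "GroundTruth",
    "DatasetSample",
    "default_ranges",
    "render_silhouette",
    "generate_dataset",
]

_TIP = 0.12          # residual tip width fraction of base_width
_MARGIN = 16         # background margin, px
_BRANCH_SPREAD = 0.22  # perpendicular divergence per axial px past the fork
_BRANCH_FACTOR = {2: 0.62, 3: 0.45}  # branch width relative to the trunk
_BLEND = 30.0        # px over which the trunk blends into branch widths

REGULAR_MAX_CURVATURE = 0.02
IRREGULAR_MIN_CURVATURE = 0.05


@dataclass
class SilhouetteSpec:
    """Generative parameters of one synthetic carrot."""

    shape_class: str = "regular"     # "regular" | "irregular"
    length: float = 420.0            # px along the midline chord
    base_width: float = 80.0         # px at the thick end
    taper: float = 1.0               # width profile exponent
    curvature: float = 0.0           # midline arc offset / length
    n_branches: int = 1              # 1-3 root tips
    branch_point: float = 0.55       # fork position, fraction of length
    broken: bool = False             # truncated with a flat cut
    break_point: float = 0.7         # cut position, fraction of length
    angle: float = 0.0               # orientation in the image, degrees
    width_wobble: float = 0.0        # relative amplitude of smooth lumps
    midline_wobble: float = 0.0      # px amplitude of smooth midline wiggle
    noise_sigma: float = 0.0         # RGB pixel noise, intensity units
    seed: int = 0

    def validate(self):
        if self.length <= self.base_width:
            raise InvalidSpecError("length must exceed base_width")
        if not 1 <= self.n_branches <= 3:
            raise InvalidSpecError("n_branches must be 1-3")
        if self.shape_class == "regular":
            if (
                self.curvature > REGULAR_MAX_CURVATURE
                or self.n_branches != 1
                or self.broken
            ):
                raise InvalidSpecError(
                    "regular shape requires curvature <= "
                    f"{REGULAR_MAX_CURVATURE}, a single root, and no break"
                )
        elif self.shape_class == "irregular":
            if not (
                self.curvature > IRREGULAR_MIN_CURVATURE
                or self.n_branches >= 2
                or self.broken
            ):
                raise InvalidSpecError(
                    "irregular shape requires curvature > "
                    f"{IRREGULAR_MIN_CURVATURE}, multiple roots, or a break"
                )
        else:
            raise InvalidSpecError(f"unknown class {self.shape_class!r}")
        return self


@dataclass
class GroundTruth:
    """Analytic description of a rendered silhouette.

    ``midline_row``/``width`` are per-column values in the *unrotated*
    frame (column index = ``column0 + i``); the mask is the rotated,
    rendered silhouette the pipeline sees.
    """

    mask: np.ndarray = field(repr=False)
    midline_row: np.ndarray = field(repr=False)
    width: np.ndarray = field(repr=False)
    column0: int = 0
    shape_class: str = "regular"
    n_roots: int = 1
    spec: SilhouetteSpec | None = None


@dataclass
class DatasetSample:
    spec: SilhouetteSpec
    truth: GroundTruth
    image: np.ndarray = field(repr=False)


def default_ranges():
    """Load the shipped morphometry/rendering defaults."""
    text = resources.files("carrotshape.data").joinpath(
        "generator_defaults.yaml"
    ).read_text()
    return yaml.safe_load(text)


def _smooth_noise(t, rng, n_harmonics=3):
    """Random low-order cosine series on [0, 1], scaled to unit max."""
    s = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        s += rng.normal() / k * np.cos(
            2.0 * math.pi * k * t + rng.uniform(0, 2 * math.pi)
        )
    peak = np.abs(s).max()
    return s / peak if peak > 0 else s


def _width_profile(spec, x, rng=None):
    t = x / spec.length
    w = spec.base_width * ((1 - t) * (1 - _TIP) + _TIP) ** spec.taper
    if spec.width_wobble > 0 and rng is not None:
        # natural root-to-root lumpiness: smooth multiplicative modulation
        w = w * (1.0 + spec.width_wobble * _smooth_noise(t, rng))
    return w


def _midline(spec, x, rng=None):
    t = x / spec.length
    f = spec.curvature * spec.length * 4.0 * t * (1.0 - t)
    if spec.midline_wobble > 0 and rng is not None:
        f = f + spec.midline_wobble * _smooth_noise(t, rng)
    return f


def render_silhouette(spec):
    """Rasterise a spec into (GroundTruth, RGB image).

    The mask is exact with respect to the analytic band: a pixel is
    foreground iff its center lies within half the local width of a
    branch midline.
    """
    spec.validate()
    L = int(round(spec.length * (spec.break_point if spec.broken else 1.0)))
    if L < 8:
        raise InvalidSpecError("silhouette too short to rasterise")
    x = np.arange(L) + 0.5
    wobble_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    w = _width_profile(spec, x, wobble_rng)
    f = _midline(spec, x, wobble_rng)

    xb = spec.branch_point * spec.length
    branches = []
    if spec.n_branches == 1:
        branches.append((f, w))
    else:
        offs = {2: (-1.0, 1.0), 3: (-1.0, 0.0, 1.0)}[spec.n_branches]
        factor = _BRANCH_FACTOR[spec.n_branches]
        past = np.clip(x - xb, 0.0, None)
        blend = np.clip(past / _BLEND, 0.0, 1.0)
        wb = w * (1.0 - (1.0 - factor) * blend)
        for d in offs:
            branches.append((f + d * _BRANCH_SPREAD * past, wb))

    lo = min(float(np.min(fj - wj / 2)) for fj, wj in branches)
    hi = max(float(np.max(fj + wj / 2)) for fj, wj in branches)

    if spec.angle:
        mask = _render_rotated(branches, x, L, lo, hi, spec.angle)
        y0 = float("nan")  # midline_row is carrot-frame only when angle == 0
    else:
        height = int(math.ceil(hi - lo)) + 2 * _MARGIN + 1
        y0 = _MARGIN - lo
        rows = np.arange(height)[:, None] + 0.5
        mask = np.zeros((height, L + 2 * _MARGIN), dtype=bool)
        body = np.zeros((height, L), dtype=bool)
        for fj, wj in branches:
            body |= np.abs(rows - (y0 + fj)[None, :]) <= wj[None, :] / 2.0
        mask[:, _MARGIN:_MARGIN + L] = body

    truth = GroundTruth(
        mask=mask,
        midline_row=y0 + f if not spec.angle else f,
        width=w,
        column0=_MARGIN,
        shape_class=spec.shape_class,
        n_roots=spec.n_branches,
        spec=spec,
    )
    return truth, _render_rgb(mask, spec)


def _render_rotated(branches, x, L, lo, hi, angle):
    """Analytic rendering at an arbitrary orientation: every output pixel
    center is inverse-rotated into the carrot frame and tested against the
    band, so rotation introduces no resampling artifacts."""
    th = math.radians(angle)
    ct, st = math.cos(th), math.sin(th)
    half_w = (L / 2) * abs(ct) + ((hi - lo) / 2) * abs(st) + _MARGIN
    half_h = (L / 2) * abs(st) + ((hi - lo) / 2) * abs(ct) + _MARGIN
    width = int(math.ceil(2 * half_w))
    height = int(math.ceil(2 * half_h))
    X = np.arange(width) + 0.5 - width / 2
    Y = (np.arange(height) + 0.5 - height / 2)[:, None]
    # inverse rotation about the band's bounding-box center
    xq = X * ct + Y * st + L / 2
    yq = -X * st + Y * ct + (lo + hi) / 2
    mask = np.zeros((height, width), dtype=bool)
    inside = (xq >= 0) & (xq <= L)
    for fj, wj in branches:
        fx = np.interp(xq, x, fj)
        wx = np.interp(xq, x, wj)
        mask |= inside & (np.abs(yq - fx) <= wx / 2.0)
    return mask


def _render_rgb(mask, spec, carrot=(230, 140, 50), background=(236, 233, 230)):
    rng = np.random.default_rng(spec.seed)
    img = np.empty(mask.shape + (3,), dtype=float)
    img[:] = background
    img[mask] = carrot
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _draw(rng, lohi):
    return float(rng.uniform(lohi[0], lohi[1]))


def _sample_spec(shape_class, rng, ranges, noise_sigma):
    common = ranges.get("common", {})
    wobble = dict(
        width_wobble=_draw(rng, common.get("width_wobble", (0.0, 0.0))),
        midline_wobble=_draw(rng, common.get("midline_wobble", (0.0, 0.0))),
    )
    if shape_class == "regular":
        r = ranges["regular"]
        return SilhouetteSpec(
            shape_class="regular",
            length=_draw(rng, r["length"]),
            base_width=_draw(rng, r["base_width"]),
            taper=_draw(rng, r["taper"]),
            curvature=_draw(rng, r["curvature"]),
            angle=_draw(rng, r["angle"]),
            noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31 - 1)),
            **wobble,
        )
    r = ranges["irregular"]
    weights = r["type_weights"]
    kinds = sorted(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    if probs.sum() <= 0:
        raise InvalidConfigError("irregular type weights sum to zero")
    kind = rng.choice(kinds, p=probs / probs.sum())

    curved = kind in ("curved", "curved_forked")
    forked = kind in ("forked", "curved_forked")
    return SilhouetteSpec(
        shape_class="irregular",
        length=_draw(rng, r["length"]),
        base_width=_draw(rng, r["base_width"]),
        taper=_draw(rng, r["taper"]),
        curvature=_draw(
            rng, r["curved_curvature"] if curved else r["mild_curvature"]
        ),
        n_branches=int(rng.integers(2, 4)) if forked else 1,
        branch_point=_draw(rng, r["branch_point"]),
        broken=kind == "broken",
        break_point=_draw(rng, r["break_point"]),
        angle=_draw(rng, r["angle"]),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
        **wobble,
    )


def generate_dataset(n_regular=56, n_irregular=79, seed=2020, ranges=None,
                     noise_sigma=None):
    """Draw a labelled dataset of rendered silhouettes.

    Returns ``(samples, table)``: a list of :class:`DatasetSample` and a
    ground-truth DataFrame (one row per sample: generative parameters,
    class, true root count).  Deterministic for a fixed seed and ranges.
    """
    if n_regular < 1 or n_irregular < 1:
        raise InvalidConfigError("need at least one sample per class")
    if ranges is None:
        ranges = default_ranges()
    if noise_sigma is None:
        noise_sigma = float(ranges.get("render", {}).get("noise_sigma", 6.0))

    rng = np.random.default_rng(seed)
    samples = []
    rows = []
    labels = ["regular"] * n_regular + ["irregular"] * n_irregular
    for i, shape_class in enumerate(labels):
        spec = _sample_spec(shape_class, rng, ranges, noise_sigma)
        truth, img = render_silhouette(spec)
        samples.append(DatasetSample(spec=spec, truth=truth, image=img))
        row = asdict(spec)
        row["sample"] = f"{shape_class[:3]}_{i:03d}"
        row["true_n_roots"] = truth.n_roots
        rows.append(row)
    table = pd.DataFrame(rows).set_index("sample")
    return samples, table


def write_dataset(samples, table, outdir):
    """Write images, masks and the ground-truth CSV to a directory."""
    import os

    from .preprocessing import write_mask
    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    for name, sample in zip(table.index, samples):
        iio.imwrite(os.path.join(outdir, f"{name}.png"), sample.image)
        write_mask(os.path.join(outdir, f"{name}_mask.png"), sample.truth.mask)
    table.to_csv(os.path.join(outdir, "ground_truth.csv"))
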