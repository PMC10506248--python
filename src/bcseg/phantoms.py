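"""Synthetic CT phantoms for the three-slice protocol.

Parametric liver / abdomen / thigh phantoms with paired ground-truth masks
for every segmentation target, so the preprocessing, network, bone-pipeline
and depot modules are all exercisable without cohort data. Geometry is built
from jittered ellipses, annuli and wobbly blobs; tissue intensities are
drawn per pixel around standard attenuation means (air about -1000 HU,
adipose about -100, muscle about 50, cortical bone about 1200) with optional
per-tissue spread and a global additive Gaussian noise term. Everything is
driven by one seed, so samples are bit-reproducible.

The phantoms are cartoons, not CT physics: no beam hardening, no partial
volume, no scanner dose modulation. They are constructed so that the mask
consistency identities hold exactly (sub-depots partition their parent
depots, marrow sits strictly inside a closed cortical shell) and so that the
thigh phantom is exactly solvable by the threshold-and-morphology bone
pipeline when noise is switched off.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .types import BinaryMask, CTSlice, SliceType

#: (mean HU, sd HU) per tissue class.
DEFAULT_TISSUE_HU: Dict[str, Tuple[float, float]] = {
    "air": (-1000.0, 0.0),
    "adipose": (-100.0, 15.0),
    "muscle": (50.0, 10.0),
    "liver": (55.0, 8.0),
    "spleen": (50.0, 8.0),
    "marrow": (-40.0, 15.0),
    "cortical": (1200.0, 100.0),
    "soft_tissue": (30.0, 10.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic slice."""

    size: Tuple[int, int] = (128, 128)
    slice_type: SliceType = SliceType.THIGH
    tissue_hu: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    noise_sd: float = 5.0
    jitter: float = 1.0          # scales all geometric jitter ranges
    fascia_visible: bool = True  # abdomen: emit DSAT/SSAT masks
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "slice_type", SliceType.coerce(self.slice_type))
        h, w = self.size
        if h % 16 or w % 16 or h < 64 or w < 64:
            raise ValueError(f"phantom size must be >= 64 and divisible by 16, got {self.size}")
        c_mean, c_sd = self.tissue_hu["cortical"]
        if not c_mean - 3 * c_sd > 400:
            raise ValueError("cortical HU must clear the 400 HU bone threshold by 3 sd")
        a_mean, a_sd = self.tissue_hu["adipose"]
        m_mean, m_sd = self.tissue_hu["muscle"]
        if a_mean + 3 * a_sd >= m_mean - 3 * m_sd:
            raise ValueError("adipose and muscle HU ranges must be separated by 3 sd")

    def noiseless(self) -> "PhantomSpec":
        """Copy with every stochastic intensity term switched off."""
        return dataclasses.replace(
            self, noise_sd=0.0,
            tissue_hu={k: (m, 0.0) for k, (m, _) in self.tissue_hu.items()})

    def with_seed(self, seed: int) -> "PhantomSpec":
        return dataclasses.replace(self, seed=int(seed))


@dataclass
class PhantomSample:
    slice: CTSlice
    masks: Dict[str, BinaryMask]
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grid(h, w):
    return np.mgrid[0:h, 0:w].astype(np.float64)


def _disk(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _ellipse_rho(yy, xx, cy, cx, ra, rb):
    return np.sqrt(((yy - cy) / ra) ** 2 + ((xx - cx) / rb) ** 2)


def _wobbly_blob(yy, xx, cy, cx, ra, rb, rng, amplitude=0.12, harmonics=(2, 3, 4)):
    """Ellipse with a smooth angular perturbation of its radius."""
    rho = _ellipse_rho(yy, xx, cy, cx, ra, rb)
    theta = np.arctan2(yy - cy, xx - cx)
    mod = np.ones_like(rho)
    for k in harmonics:
        a = rng.uniform(-amplitude, amplitude)
        phi = rng.uniform(0, 2 * np.pi)
        mod += a * np.cos(k * theta + phi)
    return rho <= mod


def _paint(tissue_of: np.ndarray, mask: np.ndarray, tissue_id: int):
    tissue_of[mask] = tissue_id


def _render(tissue_of: np.ndarray, tissue_names: List[str], spec: PhantomSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Sample per-pixel HU from the tissue map, plus global noise."""
    h, w = tissue_of.shape
    out = np.empty((h, w), dtype=np.float64)
    for tid, name in enumerate(tissue_names):
        mean, sd = spec.tissue_hu[name]
        sel = tissue_of == tid
        n = int(sel.sum())
        if n == 0:
            continue
        out[sel] = mean + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    if spec.noise_sd > 0:
        out += rng.normal(0.0, spec.noise_sd, size=out.shape)
    return np.clip(np.round(out), -1024, 3071).astype(np.int16)


# ---------------------------------------------------------------------------
# thigh
# ---------------------------------------------------------------------------

def gen_thigh(spec: PhantomSpec) -> PhantomSample:
    """Two legs: SAT rim, muscle, IMAT streaks, cortical shell, marrow."""
    if spec.slice_type is not SliceType.THIGH:
        raise ValueError("spec.slice_type must be thigh")
    h, w = spec.size
    s = min(h, w) / 128.0
    rng = np.random.default_rng(spec.seed)
    yy, xx = _grid(h, w)
    j = spec.jitter

    names = ["air", "adipose", "muscle", "cortical", "marrow"]
    AIR, ADIPOSE, MUSCLE, CORTICAL, MARROW = range(5)
    tissue = np.full((h, w), AIR, dtype=np.int8)

    sat = np.zeros((h, w), bool)
    muscle = np.zeros((h, w), bool)
    imat = np.zeros((h, w), bool)
    cortical = np.zeros((h, w), bool)
    marrow = np.zeros((h, w), bool)

    for cx_frac in (0.28, 0.72):
        cy = h * 0.5 + rng.uniform(-3, 3) * s * j
        cx = w * cx_frac + rng.uniform(-3, 3) * s * j
        r_leg = (26 + rng.uniform(-2, 2) * j) * s
        r_musc = (19 + rng.uniform(-1.5, 1.5) * j) * s
        r_cort_out = (9.5 + rng.uniform(-1, 1) * j) * s
        r_cort_in = r_cort_out - max(2.5 * s, 2.0)
        bone_cy = cy + rng.uniform(-2, 2) * s * j
        bone_cx = cx + rng.uniform(-2, 2) * s * j

        leg = _disk(yy, xx, cy, cx, r_leg)
        musc_disk = _disk(yy, xx, cy, cx, r_musc)
        cort_out = _disk(yy, xx, bone_cy, bone_cx, r_cort_out)
        cort_in = _disk(yy, xx, bone_cy, bone_cx, r_cort_in)

        leg_sat = leg & ~musc_disk
        leg_cort = cort_out & ~cort_in
        leg_marrow = cort_in
        leg_muscle_region = musc_disk & ~cort_out

        # IMAT streaks strictly inside the muscle compartment
        leg_imat = np.zeros((h, w), bool)
        for _ in range(rng.integers(3, 7)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.45, 0.8) * r_musc
            icy, icx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            if (icy - bone_cy) ** 2 + (icx - bone_cx) ** 2 < (r_cort_out + 4 * s) ** 2:
                continue
            leg_imat |= _ellipse_rho(yy, xx, icy, icx,
                                     rng.uniform(1.5, 3.0) * s,
                                     rng.uniform(1.5, 3.0) * s) <= 1
        leg_imat &= leg_muscle_region

        sat |= leg_sat
        cortical |= leg_cort
        marrow |= leg_marrow
        imat |= leg_imat
        muscle |= leg_muscle_region & ~leg_imat

    for mask, tid in ((sat, ADIPOSE), (muscle, MUSCLE), (imat, ADIPOSE),
                      (cortical, CORTICAL), (marrow, MARROW)):
        _paint(tissue, mask, tid)

    pixels = _render(tissue, names, spec, rng)
    masks = {
        "thigh_sat": BinaryMask(sat, "thigh_sat"),
        "thigh_muscle": BinaryMask(muscle, "thigh_muscle"),
        "imat": BinaryMask(imat, "imat"),
        "cortical_bone": BinaryMask(cortical, "cortical_bone"),
        "bone_marrow": BinaryMask(marrow, "bone_marrow"),
    }
    return PhantomSample(CTSlice(pixels, SliceType.THIGH), masks, spec)


# ---------------------------------------------------------------------------
# abdomen
# ---------------------------------------------------------------------------

def gen_abdomen(spec: PhantomSpec) -> PhantomSample:
    """Body ellipse with SAT ring (split by a fascia), VAT (split IPAT/RPAT),
    spine with marrow, and abdominal-wall plus paraspinal muscle."""
    if spec.slice_type is not SliceType.ABDOMEN:
        raise ValueError("spec.slice_type must be abdomen")
    h, w = spec.size
    s = min(h, w) / 128.0
    rng = np.random.default_rng(spec.seed)
    yy, xx = _grid(h, w)
    j = spec.jitter

    names = ["air", "adipose", "muscle", "cortical", "marrow", "soft_tissue"]
    AIR, ADIPOSE, MUSCLE, CORTICAL, MARROW, SOFT = range(6)
    tissue = np.full((h, w), AIR, dtype=np.int8)

    cy = h * 0.5 + rng.uniform(-2, 2) * s * j
    cx = w * 0.5 + rng.uniform(-2, 2) * s * j
    ra = (42 + rng.uniform(-3, 3) * j) * s    # semi-axis along rows
    rb = (56 + rng.uniform(-3, 3) * j) * s    # semi-axis along cols
    rho = _ellipse_rho(yy, xx, cy, cx, ra, rb)
    theta = np.arctan2(yy - cy, xx - cx)

    rho_sat_in = 0.84 + rng.uniform(-0.02, 0.02) * j
    rho_wall_in = rho_sat_in - (0.09 + rng.uniform(-0.01, 0.01) * j)

    body = rho <= 1.0
    sat = body & (rho > rho_sat_in)
    wall = (rho <= rho_sat_in) & (rho > rho_wall_in)
    interior = rho <= rho_wall_in

    # fascia of Scarpa: wobbly intermediate level inside the SAT ring
    depth = 0.5 + rng.uniform(-0.1, 0.1) * j
    wob = np.zeros_like(rho)
    for k in (2, 3):
        wob += rng.uniform(-0.015, 0.015) * j * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    rho_fascia = rho_sat_in + (1.0 - rho_sat_in) * depth + wob
    ssat = sat & (rho > rho_fascia)
    dsat = sat & ~ssat

    # spine: cortical ring with a marrow core, posterior midline
    sp_cy = cy + ra * (0.62 + rng.uniform(-0.03, 0.03) * j)
    sp_cx = cx + rng.uniform(-2, 2) * s * j
    sp_out = (8 + rng.uniform(-0.5, 0.5) * j) * s
    sp_in = sp_out - max(2.5 * s, 2.0)
    spine_out = _disk(yy, xx, sp_cy, sp_cx, sp_out)
    spine_marrow = _disk(yy, xx, sp_cy, sp_cx, sp_in)
    spine_cortical = spine_out & ~spine_marrow

    # paraspinal muscles
    paraspinal = np.zeros((h, w), bool)
    for side in (-1, 1):
        pcy = sp_cy - 2 * s
        pcx = sp_cx + side * (sp_out + (7 + rng.uniform(-1, 1) * j) * s)
        paraspinal |= _ellipse_rho(yy, xx, pcy, pcx, 6 * s, 7 * s) <= 1
    paraspinal &= interior & ~spine_out
    skeleton_muscle = wall | paraspinal

    # VAT blob in the interior, clear of spine and paraspinal muscle
    vat = _wobbly_blob(yy, xx, cy - 2 * s, cx, 0.62 * ra, 0.60 * rb, rng,
                       amplitude=0.10 * j)
    vat &= interior & ~spine_out & ~paraspinal

    # posterior boundary separating intra- from retroperitoneal fat
    y_split = cy + ra * (0.28 + rng.uniform(-0.05, 0.05) * j)
    rpat = vat & (yy >= y_split)
    ipat = vat & ~rpat

    for mask, tid in ((body, SOFT), (sat, ADIPOSE), (wall, MUSCLE),
                      (vat, ADIPOSE), (paraspinal, MUSCLE),
                      (spine_cortical, CORTICAL), (spine_marrow, MARROW)):
        _paint(tissue, mask, tid)

    pixels = _render(tissue, names, spec, rng)
    masks = {
        "sat": BinaryMask(sat, "sat"),
        "vat": BinaryMask(vat, "vat"),
        "ipat": BinaryMask(ipat, "ipat"),
        "rpat": BinaryMask(rpat, "rpat"),
        "spine_bone_marrow": BinaryMask(spine_marrow, "spine_bone_marrow"),
        "skeleton_muscle": BinaryMask(skeleton_muscle, "skeleton_muscle"),
    }
    if spec.fascia_visible:
        masks["dsat"] = BinaryMask(dsat, "dsat")
        masks["ssat"] = BinaryMask(ssat, "ssat")
    return PhantomSample(CTSlice(pixels, SliceType.ABDOMEN), masks, spec)


# ---------------------------------------------------------------------------
# liver
# ---------------------------------------------------------------------------

def gen_liver(spec: PhantomSpec) -> PhantomSample:
    """Liver blob (accurate + eroded crude masks) and a separate spleen."""
    if spec.slice_type is not SliceType.LIVER:
        raise ValueError("spec.slice_type must be liver")
    from scipy import ndimage

    h, w = spec.size
    s = min(h, w) / 128.0
    rng = np.random.default_rng(spec.seed)
    yy, xx = _grid(h, w)
    j = spec.jitter

    names = ["air", "adipose", "muscle", "liver", "spleen", "soft_tissue"]
    AIR, ADIPOSE, MUSCLE, LIVER, SPLEEN, SOFT = range(6)
    tissue = np.full((h, w), AIR, dtype=np.int8)

    cy = h * 0.5 + rng.uniform(-2, 2) * s * j
    cx = w * 0.5 + rng.uniform(-2, 2) * s * j
    ra = (44 + rng.uniform(-3, 3) * j) * s
    rb = (56 + rng.uniform(-3, 3) * j) * s
    rho = _ellipse_rho(yy, xx, cy, cx, ra, rb)
    body = rho <= 1.0
    sat_rim = body & (rho > 0.88)
    interior = rho <= 0.88

    # liver on the patient's right (image left), spleen on the left
    liver = _wobbly_blob(yy, xx, cy - 4 * s, cx - 0.38 * rb,
                         0.52 * ra, 0.40 * rb, rng, amplitude=0.10 * j)
    liver &= interior
    spleen = _wobbly_blob(yy, xx, cy - 2 * s, cx + 0.55 * rb,
                          0.22 * ra, 0.16 * rb, rng, amplitude=0.10 * j)
    spleen &= interior & ~ndimage.binary_dilation(liver, iterations=max(2, int(3 * s)))

    erosion = max(2, int(round(3 * s)))
    crude = ndimage.binary_erosion(liver, iterations=erosion)

    for mask, tid in ((body, SOFT), (sat_rim, ADIPOSE), (liver, LIVER), (spleen, SPLEEN)):
        _paint(tissue, mask, tid)

    pixels = _render(tissue, names, spec, rng)
    masks = {
        "liver_accurate": BinaryMask(liver, "liver_accurate"),
        "liver_crude": BinaryMask(crude, "liver_crude"),
        "spleen": BinaryMask(spleen, "spleen"),
    }
    return PhantomSample(CTSlice(pixels, SliceType.LIVER), masks, spec)


_GENERATORS = {
    SliceType.THIGH: gen_thigh,
    SliceType.ABDOMEN: gen_abdomen,
    SliceType.LIVER: gen_liver,
}


def generate(spec: PhantomSpec) -> PhantomSample:
    """Dispatch on ``spec.slice_type``."""
    return _GENERATORS[spec.slice_type](spec)


def gen_dataset(spec: PhantomSpec, n: int, seed: int) -> List[PhantomSample]:
    """n jittered samples of one family, reproducible from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    return [generate(spec.with_seed(cs)) for cs in child_seeds]
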