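"""Synthetic 3D cervix phantom with analytically known labels and biometry.

The phantom emulates the anatomy the parcellation protocol describes: a
curved endocervical canal running inferior from the uterine cavity (inlet,
internal os) to the vagina (outlet, external os), wrapped by a low-signal
inner stroma and an intermediate-signal outer stroma, with optional
hyperintense Nabothian cysts inside the canal (biased toward the inlet,
where they are predominantly found) and a hyperintense bladder anterior to
the cervix.  The centreline is piecewise linear — two equal segments
meeting at the canal midpoint with a configurable bend angle in the
sagittal plane — deliberately mirroring the two-line cervical-length
measurement model, so the measurement algorithm can be validated by exact
parameter recovery.

Ground truth (landmarks, cervical length, os diameters, per-label volumes)
is computed from the parametric description, never from the rasterised
arrays.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .volumes import (
    BACKGROUND,
    BLADDER,
    CANAL,
    CYST,
    INNER_STROMA,
    OUTER_STROMA,
    DEFAULT_SPACING_MM,
    IntensityVolume,
    LabelVolume,
    VoxelGeometry,
)

#: Per-label mean T2w intensity (arbitrary units) for the two acquisition
#: protocols.  Only the relative ordering is anatomically meaningful:
#: cysts/bladder hyperintense, canal mixed but brighter than stroma, inner
#: stroma dark, outer stroma intermediate and slightly lower than the
#: surrounding soft tissue (rendered as background).  The low-field preset
#: has compressed contrast and much less conspicuous cysts.
CONTRAST_PRESETS: dict[str, dict[int, float]] = {
    "high_field": {
        BACKGROUND: 0.55,
        CANAL: 0.68,
        INNER_STROMA: 0.25,
        OUTER_STROMA: 0.45,
        CYST: 0.95,
        BLADDER: 0.90,
    },
    "low_field": {
        BACKGROUND: 0.50,
        CANAL: 0.62,
        INNER_STROMA: 0.30,
        OUTER_STROMA: 0.44,
        CYST: 0.74,
        BLADDER: 0.80,
    },
}

#: Canal intensity mottling amplitude (fraction of intensity scale) per
#: preset — the mucus/mucus-plug mixture of regional high and low signal.
MOTTLE_AMPLITUDE = {"high_field": 0.22, "low_field": 0.12}

BLADDER_SEMI_AXES_MM = (12.0, 9.0, 14.0)
BLADDER_GAP_MM = 3.0


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic cervix.

    Defaults describe a mid-gestation normal cervix: ~35 mm canal, mild
    utero-cervical bend, inlet slightly wider than outlet, 4/6 mm stromal
    layers, two small inlet-biased cysts, bladder present.
    """

    canal_length: float = 35.0          # mm, true centreline (arc) length
    bend_angle: float = 20.0            # deg between inlet->mid and mid->outlet
    inlet_diameter: float = 8.0         # mm, canal diameter at the internal os
    outlet_diameter: float = 6.0        # mm, canal diameter at the external os
    canal_taper: float = 1.0            # radius interpolation exponent (1 = linear)
    inner_thickness: float = 4.0        # mm, subglandular-zone layer
    outer_thickness: float = 6.0        # mm, outer-stroma layer
    n_cysts: int = 2
    cyst_radius_range: tuple[float, float] = (1.0, 2.5)   # mm
    cyst_inlet_bias: float = 0.7        # probability mass of inlet-region placement
    include_bladder: bool = True
    contrast_preset: str = "high_field"
    noise_sd: float = 0.05              # fraction of the tissue-contrast range
    bias_field_amplitude: float = 0.2   # multiplicative smooth-field range (+/-)
    spacing: float = DEFAULT_SPACING_MM  # mm, isotropic
    margin_mm: float = 4.0              # background margin around the anatomy
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20.0 <= self.canal_length <= 50.0):
            raise PhantomError(
                f"canal_length {self.canal_length} outside the normal-cohort range [20, 50] mm"
            )
        if not (0.0 <= self.bend_angle <= 60.0):
            raise PhantomError(f"bend_angle {self.bend_angle} outside [0, 60] degrees")
        for name in ("inlet_diameter", "outlet_diameter"):
            d = getattr(self, name)
            if not (0 < d < self.canal_length):
                raise PhantomError(f"{name} {d} must be in (0, canal_length)")
        for name in ("inner_thickness", "outer_thickness"):
            t = getattr(self, name)
            if t <= self.spacing:
                raise PhantomError(f"{name} {t} must exceed the voxel spacing {self.spacing}")
        if self.contrast_preset not in CONTRAST_PRESETS:
            raise PhantomError(f"unknown contrast_preset {self.contrast_preset!r}")
        if self.spacing <= 0:
            raise PhantomError("spacing must be positive")

    # -- parametric geometry ------------------------------------------------

    def centreline(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(inlet, midpoint, outlet) world-mm points of the two-segment centreline.

        The midpoint (bend vertex) sits at the world origin; the canal runs
        superior (inlet, +z) to inferior (outlet, -z) and bends anteriorly
        (+y) within the sagittal (x = 0) plane.
        """
        half = self.canal_length / 2.0
        hb = math.radians(self.bend_angle) / 2.0
        inlet = np.array([0.0, half * math.sin(hb), half * math.cos(hb)])
        mid = np.zeros(3)
        outlet = np.array([0.0, half * math.sin(hb), -half * math.cos(hb)])
        return inlet, mid, outlet

    def canal_radius(self, t: np.ndarray | float) -> np.ndarray | float:
        """Canal radius (mm) at normalised arc position t in [0, 1] (0 = inlet)."""
        r0 = self.inlet_diameter / 2.0
        r1 = self.outlet_diameter / 2.0
        return r0 + (r1 - r0) * np.asarray(t, dtype=float) ** self.canal_taper

    def outer_radius(self) -> float:
        rmax = max(self.inlet_diameter, self.outlet_diameter) / 2.0
        return rmax + self.inner_thickness + self.outer_thickness

    # -- analytic volumes ---------------------------------------------------

    def analytic_volumes(self) -> dict[str, float]:
        """Closed-form per-layer volumes of the coaxial tapered tube (mm^3).

        Uses the tube integral pi * L * int r(t)^2 dt per shell.  The two
        segments meet at a mitred (bisector-plane) joint through the bend
        vertex, so for a taper-free tube the formula is exact at any bend
        angle (the oblique cut through the axis removes and adds congruent
        wedges); with taper the residual is second order in the radius
        change across the joint.  Cysts are excluded here and handled by
        the generator (sphere volumes subtracted from the canal).
        """
        L = self.canal_length
        r0 = self.inlet_diameter / 2.0
        dr = self.outlet_diameter / 2.0 - r0
        p = self.canal_taper
        ti, to = self.inner_thickness, self.outer_thickness
        int_r = r0 + dr / (p + 1)                       # int_0^1 r dt
        int_r2 = r0**2 + 2 * r0 * dr / (p + 1) + dr**2 / (2 * p + 1)  # int r^2 dt
        v_canal = math.pi * L * int_r2
        v_inner = math.pi * L * (2 * ti * int_r + ti**2)
        v_outer = math.pi * L * (2 * to * int_r + 2 * ti * to + to**2)
        vols = {
            "endocervical_canal": v_canal,
            "inner_stroma": v_inner,
            "outer_stroma": v_outer,
            "cyst": 0.0,
            "bladder": 0.0,
        }
        if self.include_bladder:
            a, b, c = BLADDER_SEMI_AXES_MM
            vols["bladder"] = 4.0 / 3.0 * math.pi * a * b * c
        return vols


@dataclass
class PhantomTruth:
    """Analytically known biometry and volumetry of a phantom."""

    inlet_centre: np.ndarray
    outlet_centre: np.ndarray
    canal_midpoint: np.ndarray
    true_cervical_length: float
    true_inlet_diameter: float
    true_outlet_diameter: float
    label_volumes_mm3: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("inlet_centre", "outlet_centre", "canal_midpoint"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        chord = float(np.linalg.norm(self.inlet_centre - self.outlet_centre))
        if self.true_cervical_length < chord - 1e-9:
            raise PhantomError("true cervical length below the inlet-outlet chord")

    def to_json(self) -> str:
        d = asdict(self)
        for name in ("inlet_centre", "outlet_centre", "canal_midpoint"):
            d[name] = [float(v) for v in d[name]]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# rasterisation


def _world_grid(spec: PhantomSpec) -> tuple[VoxelGeometry, np.ndarray]:
    """Voxel geometry covering the anatomy plus margin, and world coords (3, ...)."""
    inlet, _, outlet = spec.centreline()
    rout = spec.outer_radius()
    pts = [inlet, outlet, np.zeros(3)]
    lo = np.min(pts, axis=0) - rout - spec.margin_mm
    hi = np.max(pts, axis=0) + rout + spec.margin_mm
    if spec.include_bladder:
        c = _bladder_centre(spec)
        sa = np.asarray(BLADDER_SEMI_AXES_MM)
        lo = np.minimum(lo, c - sa - spec.margin_mm)
        hi = np.maximum(hi, c + sa + spec.margin_mm)
    shape = np.ceil((hi - lo) / spec.spacing).astype(int) + 1
    if np.any(shape > 256):
        raise PhantomError(f"anatomy requires grid {tuple(shape)} exceeding 256^3")
    geom = VoxelGeometry(np.full(3, spec.spacing), lo, np.eye(3))
    idx = np.indices(shape, dtype=np.float32)
    coords = lo.reshape(3, 1, 1, 1) + idx * spec.spacing
    return geom, coords


def _bladder_centre(spec: PhantomSpec) -> np.ndarray:
    inlet, _, _ = spec.centreline()
    offset = spec.outer_radius() + BLADDER_GAP_MM + BLADDER_SEMI_AXES_MM[1]
    return inlet + np.array([0.0, offset, -2.0])


def _segment_fields(coords, a, b, t0, t1, mitre_normal, mitre_side):
    """Validity mask, radial distance and global arc parameter for one segment.

    The segment is a tube around the infinite line through ``a``-``b``,
    truncated by its open end plane (perpendicular at the free end) and by
    the mitre (bisector) plane through the bend vertex — the classic mitred
    pipe joint, which tiles the elbow without gap or overlap.
    ``mitre_side`` is +1 when the free end is ``a`` (first segment, vertex
    at ``b``), -1 when the free end is ``b``.
    """
    v = b - a
    seg_len = float(np.linalg.norm(v))
    u = (v / seg_len).astype(np.float32)
    rel = coords - a.reshape(3, 1, 1, 1).astype(np.float32)
    s = np.einsum("i,i...->...", u, rel)
    vertex = b if mitre_side > 0 else a
    rel_v = coords - vertex.reshape(3, 1, 1, 1).astype(np.float32)
    side = np.einsum("i,i...->...", mitre_normal.astype(np.float32), rel_v)
    if mitre_side > 0:
        valid = (s >= 0) & (side <= 0)
    else:
        valid = (s <= seg_len) & (side >= 0)
    radial = rel - u.reshape(3, 1, 1, 1) * s[np.newaxis]
    rho = np.sqrt(np.einsum("i...,i...->...", radial, radial))
    t = t0 + (t1 - t0) * np.clip(s / seg_len, 0.0, 1.0)
    return valid, rho, t


def _rasterise_labels(spec: PhantomSpec, coords: np.ndarray) -> np.ndarray:
    inlet, mid, outlet = spec.centreline()
    u1 = (mid - inlet) / np.linalg.norm(mid - inlet)
    u2 = (outlet - mid) / np.linalg.norm(outlet - mid)
    mitre = u1 + u2
    mitre /= np.linalg.norm(mitre)
    canal = np.zeros(coords.shape[1:], dtype=bool)
    inner = np.zeros_like(canal)
    outer = np.zeros_like(canal)
    for a, b, t0, t1, mside in (
        (inlet, mid, 0.0, 0.5, +1),
        (mid, outlet, 0.5, 1.0, -1),
    ):
        valid, rho, t = _segment_fields(coords, a, b, t0, t1, mitre, mside)
        r = spec.canal_radius(t)
        canal |= valid & (rho <= r)
        inner |= valid & (rho <= r + spec.inner_thickness)
        outer |= valid & (rho <= r + spec.inner_thickness + spec.outer_thickness)
    lab = np.zeros(coords.shape[1:], dtype=np.int16)
    lab[outer] = OUTER_STROMA
    lab[inner] = INNER_STROMA
    lab[canal] = CANAL
    return lab


def _arc_point(spec: PhantomSpec, t: float) -> np.ndarray:
    """World point at normalised arc position t along the two-segment centreline."""
    inlet, mid, outlet = spec.centreline()
    if t <= 0.5:
        return inlet + (mid - inlet) * (t / 0.5)
    return mid + (outlet - mid) * ((t - 0.5) / 0.5)


def _place_cysts(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, float]]:
    """Cyst (centre, radius) pairs entirely inside the canal lumen."""
    cysts: list[tuple[np.ndarray, float]] = []
    inlet, mid, outlet = spec.centreline()
    for _ in range(spec.n_cysts):
        radius = float(rng.uniform(*spec.cyst_radius_range))
        if rng.uniform() < spec.cyst_inlet_bias:
            t = float(rng.beta(1.5, 6.0))  # concentrated toward the inlet
        else:
            t = float(rng.uniform())
        tmin = radius / spec.canal_length
        t = float(np.clip(t, tmin, 1.0 - tmin))
        r_canal = float(spec.canal_radius(t))
        radius = min(radius, 0.85 * r_canal)
        if radius < 0.6 * spec.spacing:
            continue  # too small to rasterise meaningfully
        centre = _arc_point(spec, t)
        slack = max(0.0, r_canal - radius)
        if slack > 0:
            axis = (mid - inlet) if t <= 0.5 else (outlet - mid)
            axis = axis / np.linalg.norm(axis)
            perp = np.cross(axis, np.array([1.0, 0.0, 0.0]))
            perp /= np.linalg.norm(perp)
            perp2 = np.cross(axis, perp)
            ang = rng.uniform(0, 2 * math.pi)
            off = rng.uniform(0, 0.8 * slack)
            centre = centre + off * (math.cos(ang) * perp + math.sin(ang) * perp2)
        cysts.append((centre, radius))
    return cysts


def _smooth_noise(shape, rng: np.random.Generator, sigma_vox: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape).astype(np.float32), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def _bias_field(coords: np.ndarray, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Multiplicative smooth field 1 + amplitude * p(x,y,z), p a random quadratic."""
    lo = coords.reshape(3, -1).min(axis=1)
    hi = coords.reshape(3, -1).max(axis=1)
    xn = [(coords[i] - lo[i]) / max(hi[i] - lo[i], 1e-9) * 2 - 1 for i in range(3)]
    terms = [np.ones_like(xn[0])]
    terms += xn
    terms += [xn[i] * xn[j] for i in range(3) for j in range(i, 3)]
    coef = rng.uniform(-1, 1, size=len(terms)).astype(np.float32)
    coef[0] = 0.0
    p = sum(c * t for c, t in zip(coef, terms))
    peak = np.abs(p).max()
    if peak > 0:
        p = p / peak
    return 1.0 + amplitude * p


def _render_intensity(
    spec: PhantomSpec, lab: np.ndarray, coords: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    preset = CONTRAST_PRESETS[spec.contrast_preset]
    img = np.empty(lab.shape, dtype=np.float32)
    for code, mean in preset.items():
        img[lab == code] = mean
    # mucus heterogeneity: smooth mottling restricted to the canal
    mottle_sigma = 2.0 / spec.spacing
    mottle = _smooth_noise(lab.shape, rng, mottle_sigma) * MOTTLE_AMPLITUDE[spec.contrast_preset]
    canal_mask = lab == CANAL
    img[canal_mask] += mottle[canal_mask]
    img *= _bias_field(coords, rng, spec.bias_field_amplitude)
    contrast_range = max(preset.values()) - min(preset.values())
    img += rng.normal(0.0, spec.noise_sd * contrast_range, size=lab.shape).astype(np.float32)
    return np.clip(img, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume, PhantomTruth]:
    """Rasterise a phantom: T2w-like image, label map, and analytic truth.

    Determinism contract: identical specs (including seed) give bit-identical
    volumes; the truth never depends on the rasterisation.
    """
    rng = np.random.default_rng(spec.seed)
    geom, coords = _world_grid(spec)
    lab = _rasterise_labels(spec, coords)

    cysts = _place_cysts(spec, rng)
    cyst_volume = 0.0
    canal_mask = lab == CANAL
    for centre, radius in cysts:
        rel = coords - centre.reshape(3, 1, 1, 1).astype(np.float32)
        inside = np.einsum("i...,i...->...", rel, rel) <= radius**2
        lab[inside & canal_mask] = CYST
        cyst_volume += 4.0 / 3.0 * math.pi * radius**3

    if spec.include_bladder:
        c = _bladder_centre(spec)
        sa = np.asarray(BLADDER_SEMI_AXES_MM, dtype=np.float32)
        rel = (coords - c.reshape(3, 1, 1, 1).astype(np.float32)) / sa.reshape(3, 1, 1, 1)
        inside = np.einsum("i...,i...->...", rel, rel) <= 1.0
        lab[inside & (lab == BACKGROUND)] = BLADDER

    img = _render_intensity(spec, lab, coords, rng)

    vols = spec.analytic_volumes()
    vols["cyst"] = cyst_volume
    vols["endocervical_canal"] = vols["endocervical_canal"] - cyst_volume
    vols["total_canal"] = vols["endocervical_canal"] + vols["cyst"]
    inlet, mid, outlet = spec.centreline()
    truth = PhantomTruth(
        inlet_centre=inlet,
        outlet_centre=outlet,
        canal_midpoint=mid,
        true_cervical_length=spec.canal_length,
        true_inlet_diameter=spec.inlet_diameter,
        true_outlet_diameter=spec.outlet_diameter,
        label_volumes_mm3=vols,
    )
    return IntensityVolume(img, geom), LabelVolume(lab, geom), truth


# ---------------------------------------------------------------------------
# cohort simulation


#: Gestational-age effects (per week) encoded in the synthetic normative
#: cohort: cervical length shortens while the internal-os (inlet) diameter
#: widens as the cervix remodels toward term; the outlet diameter drifts
#: slightly.  Between-subject SDs give the wide normal anatomical variance
#: seen across the charts.
DEFAULT_GA_EFFECTS = {
    "canal_length": {"intercept_at_16w": 40.0, "slope_per_week": -0.3, "sd": 2.5},
    "inlet_diameter": {"intercept_at_16w": 6.0, "slope_per_week": 0.1, "sd": 0.7},
    "outlet_diameter": {"intercept_at_16w": 6.0, "slope_per_week": -0.02, "sd": 0.6},
}

ETHNICITIES = ("white", "asian", "black", "other")
ETHNICITY_P = (0.80, 0.10, 0.07, 0.03)
CYST_PREVALENCE = 0.36          # fraction of cases with detectable cysts
LOW_FIELD_FRACTION = 0.47       # 0.55T share of the acquisition mix


@dataclass
class CohortCase:
    """One simulated subject: spec + truth (+ optionally rasterised volumes)."""

    subject_id: str
    ga: float
    covariates: dict
    spec: PhantomSpec
    truth: PhantomTruth
    image: IntensityVolume | None = None
    labels: LabelVolume | None = None


def generate_cohort(
    n: int,
    ga_range: tuple[float, float] = (16.0, 40.0),
    seed: int = 0,
    ga_effects: dict | None = None,
    rasterise: bool = True,
    spacing: float = DEFAULT_SPACING_MM,
) -> list[CohortCase]:
    """Simulate a normative cohort with recorded true gestational-age effects.

    Geometry truth depends only on GA and subject-level noise; the
    field-strength covariate switches the contrast preset and never touches
    geometry.  With ``rasterise=False`` only specs and analytic truths are
    produced (sufficient for chart fitting, and much faster).
    """
    if n < 1:
        raise PhantomError("cohort size must be >= 1")
    lo, hi = ga_range
    if not (16.0 <= lo < hi <= 40.0):
        raise PhantomError(f"ga_range {ga_range} outside [16, 40] weeks")
    eff = ga_effects or DEFAULT_GA_EFFECTS
    rng = np.random.default_rng(seed)
    cases: list[CohortCase] = []
    for i in range(n):
        ga = float(rng.uniform(lo, hi))
        dw = ga - 16.0

        def draw(name, lo_clip, hi_clip):
            e = eff[name]
            mu = e["intercept_at_16w"] + e["slope_per_week"] * dw
            return float(np.clip(rng.normal(mu, e["sd"]), lo_clip, hi_clip))

        length = draw("canal_length", 21.0, 49.0)
        inlet_d = draw("inlet_diameter", 3.5, 12.5)
        outlet_d = draw("outlet_diameter", 3.0, min(12.0, inlet_d + 3.0))
        bend = float(np.clip(rng.normal(20.0, 10.0), 0.0, 45.0))
        inner_t = float(np.clip(rng.normal(4.0, 0.5), 1.5 * spacing, 7.0))
        outer_t = float(np.clip(rng.normal(6.0, 0.8), 1.5 * spacing, 10.0))
        has_cysts = rng.uniform() < CYST_PREVALENCE
        n_cysts = int(1 + rng.poisson(0.7)) if has_cysts else 0
        field = 0.55 if rng.uniform() < LOW_FIELD_FRACTION else 3.0
        age = float(np.clip(rng.normal(33.0, 4.5), 21.0, 47.0))
        height = float(np.clip(rng.normal(165.0, 6.5), 145.0, 190.0))
        bmi = float(np.clip(rng.normal(26.0, 4.0), 17.0, 40.0))
        weight = bmi * (height / 100.0) ** 2
        ethnicity = str(rng.choice(ETHNICITIES, p=ETHNICITY_P))

        spec = PhantomSpec(
            canal_length=length,
            bend_angle=bend,
            inlet_diameter=inlet_d,
            outlet_diameter=outlet_d,
            inner_thickness=inner_t,
            outer_thickness=outer_t,
            n_cysts=n_cysts,
            contrast_preset="low_field" if field == 0.55 else "high_field",
            spacing=spacing,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if rasterise:
            image, labels, truth = generate_phantom(spec)
        else:
            image = labels = None
            _, _, truth = _truth_only(spec)
        cases.append(
            CohortCase(
                subject_id=f"sim{i:04d}",
                ga=ga,
                covariates={
                    "field_strength": field,
                    "maternal_age": age,
                    "height": height,
                    "weight": weight,
                    "bmi": bmi,
                    "ethnicity": ethnicity,
                },
                spec=spec,
                truth=truth,
                image=image,
                labels=labels,
            )
        )
    return cases


def _truth_only(spec: PhantomSpec):
    """Analytic truth without rasterisation (cyst placement still seeded)."""
    rng = np.random.default_rng(spec.seed)
    cysts = _place_cysts(spec, rng)
    cyst_volume = sum(4.0 / 3.0 * math.pi * r**3 for _, r in cysts)
    vols = spec.analytic_volumes()
    vols["cyst"] = cyst_volume
    vols["endocervical_canal"] -= cyst_volume
    vols["total_canal"] = vols["endocervical_canal"] + vols["cyst"]
    inlet, mid, outlet = spec.centreline()
    truth = PhantomTruth(
        inlet_centre=inlet,
        outlet_centre=outlet,
        canal_midpoint=mid,
        true_cervical_length=spec.canal_length,
        true_inlet_diameter=spec.inlet_diameter,
        true_outlet_diameter=spec.outlet_diameter,
        label_volumes_mm3=vols,
    )
    return None, None, truth
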