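"""Synthetic well-plate image generator with known ground truth.

This module emulates the acquisition geometry of a widefield mesoscopic
fluorescence imaging system pointed at multi-well plates of 3D tumor-spheroid
cultures, so that every downstream stage (dark subtraction, excitation-leakage
correction, background-statistics segmentation, dose-response fitting) can be
verified by parameter recovery against planted values.

Physical picture
----------------
Each well is rendered as its own camera crop. Spheroid clusters are
hemispherical caps; because widefield imaging integrates emission along the
optical path, the per-pixel emission strength is proportional to the local
cap thickness ``sqrt(r**2 - d**2)``, times an uptake coefficient, times the
administered drug concentration. Cell-free culture media contributes a small
uniform background (a few percent of the peak cluster signal). Two morphology
archetypes are provided: ``compact`` (few dense, round, uniform aggregates,
as oral squamous carcinoma SCC-type cultures form) and ``dispersed`` (more,
smaller, more variable clusters, as ovarian SKOV-3-type cultures form).

The camera model is::

    fluorescence : dark + vignetting * (gain * emission + g * leakage) + noise
    nd_reference : dark + vignetting * leakage + noise
    dark         : dark + noise

where ``g`` is the true multiplicative fraction of the excitation/reflection
light pattern that bleeds through the emission filter, and ``leakage`` is a
spatially structured excitation pattern (smooth in-well base plus
high-intensity arcs at the plastic well rim, where reflections concentrate).
The matched-OD neutral-density reference channel sees the excitation pattern
itself, which is what makes the through-origin regression of fluorescence on
ND frames over fluorophore-free calibration wells identifiable.

Noise is Poisson shot noise on the pre-noise expectation plus additive
Gaussian read noise (a standard EMCCD approximation), with an optional
relative (multiplicative) Gaussian term used for calibration studies. All
randomness flows through explicit integer seeds; identical seeds give
identical output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError
from .frames import ImageFrame, check_conformable
from .imgcorr import CalibrationSet

__all__ = [
    "MorphologyArchetype",
    "COMPACT",
    "DISPERSED",
    "GroundTruthWell",
    "OpticsParams",
    "NoiseParams",
    "default_leakage_pattern",
    "generate_spheroid_field",
    "render_channel_image",
    "generate_calibration_set",
    "generate_dose_response_experiment",
    "ExperimentBundle",
    "SimulatedWell",
    "simulate_plate_reader",
    "DEFAULT_CONCENTRATIONS",
    "DEFAULT_UPTAKE_COEFFICIENT",
    "DEFAULT_MEDIA_BACKGROUND",
]

#: administered LC-Dox-PoP concentrations of the study design, μg/mL
DEFAULT_CONCENTRATIONS = (1.0, 3.0, 6.0, 9.0)

#: emission units per (μg/mL × pixel of optical path length)
DEFAULT_UPTAKE_COEFFICIENT = 5.0

#: uniform media autofluorescence, emission units (~3% of the 9 μg/mL peak)
DEFAULT_MEDIA_BACKGROUND = 9.5


@dataclass(frozen=True)
class MorphologyArchetype:
    """Statistical description of how a cell model aggregates in culture.

    Parameters
    ----------
    cluster_count_range:
        Inclusive (min, max) number of spheroid clusters per well.
    radius_mean, radius_spread:
        Mean and SD of the cluster cap radius, pixels.
    packing_density:
        In (0, 1]; higher values confine cluster centres to a smaller
        placement disk (dense, centralised aggregation).
    thickness_scale:
        Multiplier on the hemispherical-cap thickness (arbitrary length
        units per pixel of radius); flatter, loosely adherent clusters
        use values < 1.
    """

    name: str
    cluster_count_range: tuple[int, int]
    radius_mean: float
    radius_spread: float
    packing_density: float
    thickness_scale: float

    def __post_init__(self) -> None:
        lo, hi = self.cluster_count_range
        if not (0 < lo <= hi):
            raise ValueError("cluster_count_range must satisfy 0 < min <= max")
        if self.radius_mean <= 0:
            raise ValueError("radius_mean must be positive")
        if not 0 < self.packing_density <= 1:
            raise ValueError("packing_density must be in (0, 1]")
        if self.thickness_scale <= 0:
            raise ValueError("thickness_scale must be positive")


#: dense, uniform, rounded aggregates (SCC-like)
COMPACT = MorphologyArchetype(
    name="compact",
    cluster_count_range=(4, 8),
    radius_mean=7.0,
    radius_spread=1.5,
    packing_density=0.85,
    thickness_scale=1.0,
)

#: more numerous, smaller, more variable clusters (SKOV-3-like)
DISPERSED = MorphologyArchetype(
    name="dispersed",
    cluster_count_range=(8, 16),
    radius_mean=4.5,
    radius_spread=2.0,
    packing_density=0.45,
    thickness_scale=0.7,
)

_ARCHETYPES = {"compact": COMPACT, "dispersed": DISPERSED}


def get_archetype(name: str) -> MorphologyArchetype:
    try:
        return _ARCHETYPES[name]
    except KeyError:
        raise ValueError(
            f"unknown archetype {name!r}; expected one of {sorted(_ARCHETYPES)}"
        ) from None


@dataclass
class GroundTruthWell:
    """Planted truth for one simulated well.

    ``fluorophore_map`` is the true per-pixel emission strength:
    ``media_background`` everywhere, plus
    ``uptake_coefficient * concentration * thickness_map`` inside clusters.
    """

    fluorophore_map: np.ndarray
    thickness_map: np.ndarray
    cluster_mask: np.ndarray
    administered_concentration: float
    uptake_coefficient: float = DEFAULT_UPTAKE_COEFFICIENT
    media_background: float = DEFAULT_MEDIA_BACKGROUND
    n_clusters: int = 0  # drawn count; overlapping caps may merge in the mask

    def __post_init__(self) -> None:
        self.fluorophore_map = np.asarray(self.fluorophore_map, dtype=float)
        self.thickness_map = np.asarray(self.thickness_map, dtype=float)
        self.cluster_mask = np.asarray(self.cluster_mask, dtype=bool)
        check_conformable(self.fluorophore_map, self.thickness_map)
        check_conformable(self.fluorophore_map, self.cluster_mask)
        if self.administered_concentration < 0:
            raise ValueError("administered_concentration must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fluorophore_map.shape  # type: ignore[return-value]

    def mean_cluster_thickness(self) -> float:
        """Mean optical thickness over cluster pixels (0 if no clusters)."""
        if not self.cluster_mask.any():
            return 0.0
        return float(self.thickness_map[self.cluster_mask].mean())

    def scaled_emission(self, factor: float) -> "GroundTruthWell":
        """Truth with the drug-associated emission scaled by ``factor``.

        The uniform media background is autofluorescence, not fluorophore,
        so it is left untouched; used to plant photobleaching.
        """
        drug = self.fluorophore_map - self.media_background
        return replace(self, fluorophore_map=self.media_background + factor * drug)


def default_leakage_pattern(
    grid_shape: tuple[int, int],
    *,
    base: float = 500.0,
    ring_amplitude: float = 1500.0,
    ring_radius_frac: float = 0.47,
    ring_sigma_px: float = 2.5,
    n_arcs: int = 3,
) -> np.ndarray:
    """Excitation-light pattern seen by the ND reference channel.

    A uniform in-well base level plus bright arcs on a ring near the frame
    edge, mimicking reflections off the plastic well rim. Deterministic in
    its arguments.
    """
    ny, nx = grid_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rho = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    ring_radius = ring_radius_frac * min(ny, nx)
    ring = np.exp(-0.5 * ((rho - ring_radius) / ring_sigma_px) ** 2)
    # n_arcs bright arcs: clipped raised cosine so parts of the rim are dark
    arcs = np.clip(1.5 * np.cos(n_arcs * theta) - 0.5, 0.0, 1.0)
    return base + ring_amplitude * ring * arcs


@dataclass
class OpticsParams:
    """Detector and illumination model shared by all frames of a session."""

    gain: float = 100.0  # counts per emission unit
    leakage_fraction: float = 0.91  # g: excitation bleed-through multiplier
    leakage_pattern: np.ndarray | None = None  # None -> default for the shape
    dark_level: float = 100.0  # counts
    vignetting_profile: np.ndarray | None = None  # None -> flat (all ones)
    nd_contamination: float = 0.0  # emission fraction passing the ND filter

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.leakage_fraction < 0:
            raise ValueError("leakage_fraction must be nonnegative")
        if self.dark_level < 0:
            raise ValueError("dark_level must be nonnegative")
        if self.leakage_pattern is not None:
            lp = np.asarray(self.leakage_pattern, dtype=float)
            if not np.all(np.isfinite(lp)) or (lp < 0).any():
                raise ValueError("leakage_pattern must be finite and nonnegative")
            self.leakage_pattern = lp
        if self.vignetting_profile is not None:
            v = np.asarray(self.vignetting_profile, dtype=float)
            if (v <= 0).any() or (v > 1).any():
                raise ValueError("vignetting_profile values must be in (0, 1]")
            self.vignetting_profile = v

    def resolved_leakage(self, shape: tuple[int, int]) -> np.ndarray:
        if self.leakage_pattern is None:
            return default_leakage_pattern(shape)
        check_conformable(self.leakage_pattern, np.empty(shape))
        return self.leakage_pattern

    def resolved_vignetting(self, shape: tuple[int, int]) -> np.ndarray:
        if self.vignetting_profile is None:
            return np.ones(shape)
        check_conformable(self.vignetting_profile, np.empty(shape))
        return self.vignetting_profile


@dataclass
class NoiseParams:
    """Sensor-noise model: Poisson shot + Gaussian read (+ optional relative)."""

    shot_noise_enabled: bool = True
    read_noise_sd: float = 5.0  # counts
    relative_noise_frac: float = 0.0  # SD as a fraction of the expectation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be nonnegative")
        if self.relative_noise_frac < 0:
            raise ValueError("relative_noise_frac must be nonnegative")


#: noiseless configuration, for exactness tests
NOISELESS = NoiseParams(shot_noise_enabled=False, read_noise_sd=0.0, seed=0)


def generate_spheroid_field(
    archetype: MorphologyArchetype | str,
    grid_shape: tuple[int, int],
    concentration: float,
    seed: int,
    *,
    uptake_coefficient: float = DEFAULT_UPTAKE_COEFFICIENT,
    media_background: float = DEFAULT_MEDIA_BACKGROUND,
) -> GroundTruthWell:
    """Draw a random spheroid field and its planted emission map.

    Cluster count is uniform over the archetype's inclusive range; radii are
    normal (clipped to keep caps on-grid); centres are uniform in a placement
    disk whose area scales with total cluster area over ``packing_density``,
    capped so clusters stay inside the analysable well region. Thickness maps
    of overlapping caps add, as stacked cell layers would along the optical
    path.
    """
    if isinstance(archetype, str):
        archetype = get_archetype(archetype)
    ny, nx = grid_shape
    if ny <= 0 or nx <= 0:
        raise ValueError(f"grid_shape must be positive, got {grid_shape}")
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")

    rng = np.random.default_rng(seed)
    lo, hi = archetype.cluster_count_range
    n_clusters = int(rng.integers(lo, hi + 1))

    r_mean, r_sd = archetype.radius_mean, archetype.radius_spread
    r_max_allowed = 1.8 * r_mean
    radii = np.clip(rng.normal(r_mean, r_sd, size=n_clusters), 1.5, r_max_allowed)

    # placement disk sized by total cluster area / packing density, capped so
    # cluster extent stays well inside the frame (clear of the rim and of the
    # background ROIs used downstream)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    placement_radius = min(
        np.sqrt(n_clusters * r_mean**2 / archetype.packing_density),
        0.17 * min(ny, nx),
    )
    angles = rng.uniform(0, 2 * np.pi, size=n_clusters)
    dists = placement_radius * np.sqrt(rng.uniform(0, 1, size=n_clusters))
    centers = np.column_stack([cy + dists * np.sin(angles), cx + dists * np.cos(angles)])

    yy, xx = np.mgrid[0:ny, 0:nx]
    thickness = np.zeros((ny, nx))
    for (ycen, xcen), r in zip(centers, radii):
        d2 = (yy - ycen) ** 2 + (xx - xcen) ** 2
        thickness += archetype.thickness_scale * np.sqrt(np.maximum(0.0, r**2 - d2))

    cluster_mask = thickness > 0
    fluorophore = media_background + uptake_coefficient * concentration * thickness
    return GroundTruthWell(
        fluorophore_map=fluorophore,
        thickness_map=thickness,
        cluster_mask=cluster_mask,
        administered_concentration=concentration,
        uptake_coefficient=uptake_coefficient,
        media_background=media_background,
        n_clusters=n_clusters,
    )


def blank_well(
    grid_shape: tuple[int, int],
    concentration: float,
    *,
    uptake_coefficient: float = DEFAULT_UPTAKE_COEFFICIENT,
    media_background: float = DEFAULT_MEDIA_BACKGROUND,
    extracellular_path: float = 0.1,
) -> GroundTruthWell:
    """Cell-free drug-only well: uniform extracellular drug fluorescence.

    The thin media layer is modelled as a uniform optical path of
    ``extracellular_path`` pixels, so the drug term stays small relative to
    cluster signal.
    """
    thickness = np.zeros(grid_shape)
    fluorophore = np.full(
        grid_shape,
        media_background + uptake_coefficient * concentration * extracellular_path,
    )
    return GroundTruthWell(
        fluorophore_map=fluorophore,
        thickness_map=thickness,
        cluster_mask=np.zeros(grid_shape, dtype=bool),
        administered_concentration=concentration,
        uptake_coefficient=uptake_coefficient,
        media_background=media_background,
    )


def _apply_noise(
    expected: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    out = expected
    if noise.shot_noise_enabled:
        out = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=expected.shape)
    if noise.relative_noise_frac > 0:
        out = out + rng.normal(0.0, 1.0, size=expected.shape) * (
            noise.relative_noise_frac * expected
        )
    return np.asarray(out, dtype=float)


def render_channel_image(
    truth: GroundTruthWell,
    optics: OpticsParams,
    noise: NoiseParams,
    channel_role: str,
    *,
    channel: str = "dox",
    timepoint: str = "calibration",
    well_id: str = "",
    rng: np.random.Generator | None = None,
) -> ImageFrame:
    """Render one camera frame from ground truth under the optics model.

    ``channel_role`` selects the filter in front of the detector:
    ``fluorescence`` (emission filter: sees gain × emission plus the
    g-scaled excitation leakage), ``nd_reference`` (matched-OD ND filter:
    sees the excitation pattern only, plus any configured contamination), or
    ``dark`` (shutter closed).
    """
    shape = truth.shape
    vign = optics.resolved_vignetting(shape)
    leak = optics.resolved_leakage(shape)
    if channel_role == "fluorescence":
        expected = optics.dark_level + vign * (
            optics.gain * truth.fluorophore_map + optics.leakage_fraction * leak
        )
    elif channel_role == "nd_reference":
        expected = optics.dark_level + vign * (
            leak + optics.nd_contamination * optics.gain * truth.fluorophore_map
        )
    elif channel_role == "dark":
        expected = np.full(shape, optics.dark_level)
    else:
        raise ValueError(
            f"unknown channel_role {channel_role!r}; "
            "expected fluorescence, nd_reference or dark"
        )
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    pixels = _apply_noise(expected, noise, rng)
    return ImageFrame(
        pixels=pixels,
        channel=channel,
        filter_role=channel_role,
        timepoint=timepoint,
        well_id=well_id,
    )


def generate_calibration_set(
    optics: OpticsParams,
    noise: NoiseParams,
    n_wells: int,
    seed: int,
    *,
    grid_shape: tuple[int, int] = (128, 128),
    n_dark_frames: int = 3,
    channel: str = "dox",
) -> CalibrationSet:
    """Simulate a calibration session: water wells + dark frames.

    Water-filled wells contain no fluorophore, so after dark subtraction the
    fluorescence frame is the planted fraction ``g`` times the ND frame (up
    to noise) — the identifiability condition for the leakage estimator. The
    planted ``g`` is carried on the returned set for recovery tests.
    """
    if n_wells < 1:
        raise ValueError(f"n_wells must be >= 1, got {n_wells}")
    rng = np.random.default_rng(seed)
    water = GroundTruthWell(
        fluorophore_map=np.zeros(grid_shape),
        thickness_map=np.zeros(grid_shape),
        cluster_mask=np.zeros(grid_shape, dtype=bool),
        administered_concentration=0.0,
        media_background=0.0,
    )
    pairs = []
    for i in range(n_wells):
        wid = f"CAL{i + 1}"
        f = render_channel_image(
            water, optics, noise, "fluorescence",
            channel=channel, well_id=wid, rng=rng,
        )
        nd = render_channel_image(
            water, optics, noise, "nd_reference",
            channel=channel, well_id=wid, rng=rng,
        )
        pairs.append((f, nd))
    darks = [
        render_channel_image(
            water, optics, noise, "dark",
            channel=channel, well_id=f"DARK{i + 1}", rng=rng,
        )
        for i in range(n_dark_frames)
    ]
    return CalibrationSet(
        dark_frames=darks,
        water_well_pairs=pairs,
        drug_only_frames=[],
        planted_leakage_fraction=optics.leakage_fraction,
    )


@dataclass
class SimulatedWell:
    """One imaged well of a simulated experiment, with its ground truth."""

    well_id: str
    role: str  # treatment | control | blank
    concentration: float
    truth: GroundTruthWell
    frames: list[ImageFrame] = field(default_factory=list)
    truth_post: dict[str, GroundTruthWell] = field(default_factory=dict)

    def get_frame(self, channel: str, filter_role: str, timepoint: str) -> ImageFrame:
        for fr in self.frames:
            if (fr.channel, fr.filter_role, fr.timepoint) == (
                channel, filter_role, timepoint,
            ):
                return fr
        raise KeyError(
            f"well {self.well_id}: no frame ({channel}, {filter_role}, {timepoint})"
        )


@dataclass
class ExperimentBundle:
    """A full simulated dose-response experiment with attached ground truth."""

    wells: list[SimulatedWell]
    calibration: dict[str, CalibrationSet]
    optics: OpticsParams
    noise: NoiseParams
    concentrations: tuple[float, ...]
    bleach_factor: float
    seed: int
    grid_shape: tuple[int, int]

    def treatment_wells(self) -> list[SimulatedWell]:
        return [w for w in self.wells if w.role == "treatment"]

    def all_frames(self) -> list[ImageFrame]:
        return [fr for w in self.wells for fr in w.frames]

    def concentration_map(self) -> dict[str, float]:
        return {w.well_id: w.concentration for w in self.wells}

    def role_map(self) -> dict[str, str]:
        return {w.well_id: w.role for w in self.wells}

    def expected_mean_signal(
        self, well: SimulatedWell, channel: str, timepoint: str
    ) -> float:
        """Noiseless expected mean corrected signal over the true cluster mask.

        The generator's analytic expectation: gain × (uptake × concentration
        × mean cluster thickness + media background), with the porphyrin
        post-activation emission scaled by the planted bleach factor. Residual
        leakage (identical across wells) is excluded: it shifts the intercept
        of a dose-response fit, not the slope.
        """
        truth = well.truth
        factor = 1.0
        if channel == "pop" and timepoint == "post_activation":
            factor = self.bleach_factor
        t_mean = truth.mean_cluster_thickness()
        return self.optics.gain * (
            factor * truth.uptake_coefficient * well.concentration * t_mean
            + truth.media_background
        )

    def planted_slope(self, channel: str = "dox", timepoint: str = "post_activation") -> float:
        """OLS slope of the noiseless expected means on concentration.

        This is the dose-response slope a perfect measurement chain would
        recover for this seed's geometry; comparing the pipeline's fitted
        slope against it isolates measurement error from morphological
        sampling variation.
        """
        wells = self.treatment_wells()
        x = np.array([w.concentration for w in wells])
        y = np.array([self.expected_mean_signal(w, channel, timepoint) for w in wells])
        xc = x - x.mean()
        return float((xc * y).sum() / (xc**2).sum())


def generate_dose_response_experiment(
    concentrations,
    archetype: MorphologyArchetype | str,
    optics: OpticsParams,
    noise: NoiseParams,
    seed: int,
    *,
    bleach_factor: float = 0.9,
    grid_shape: tuple[int, int] = (128, 128),
    uptake_coefficient: float = DEFAULT_UPTAKE_COEFFICIENT,
    media_background: float = DEFAULT_MEDIA_BACKGROUND,
    n_calibration_wells: int = 4,
    channels: tuple[str, ...] = ("dox", "pop"),
    shared_field_seed: int | None = None,
) -> ExperimentBundle:
    """Simulate the full study design for one imaging session.

    One treatment well per administered concentration, plus a drug-free
    control well and a cell-free drug-only blank. Doxorubicin is imaged
    post-activation (release reporter); porphyrin is imaged pre- and
    post-activation with its post emission scaled by ``bleach_factor`` < 1
    (planted photobleaching). Each imaged (channel, timepoint) produces a
    fluorescence/ND frame pair; a calibration session is attached per
    channel.

    ``shared_field_seed`` forces the identical spheroid geometry into every
    cell-bearing well (only the concentration differs); with noise disabled
    this makes the quantified means exactly linear in concentration, the
    configuration used by exactness tests.
    """
    concentrations = tuple(float(c) for c in concentrations)
    if len(concentrations) == 0:
        raise ValueError("concentrations must be non-empty")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be nonnegative")
    if not 0 < bleach_factor <= 1:
        raise ValueError("bleach_factor must be in (0, 1]")
    if isinstance(archetype, str):
        archetype = get_archetype(archetype)

    master = np.random.default_rng(seed)
    # independent child seeds below 2**31 for every stochastic component
    def child_seed() -> int:
        return int(master.integers(0, 2**31 - 1))

    calibration = {
        ch: generate_calibration_set(
            optics, noise, n_calibration_wells, child_seed(),
            grid_shape=grid_shape, channel=ch,
        )
        for ch in channels
    }

    def imaged_timepoints(ch: str) -> tuple[str, ...]:
        return ("post_activation",) if ch == "dox" else ("pre_activation", "post_activation")

    wells: list[SimulatedWell] = []
    specs = [(f"W{i + 1}", "treatment", c) for i, c in enumerate(concentrations)]
    specs.append(("CTRL", "control", 0.0))
    specs.append(("BLANK", "blank", max(concentrations)))
    for well_id, role, conc in specs:
        if role == "blank":
            truth = blank_well(
                grid_shape, conc,
                uptake_coefficient=uptake_coefficient,
                media_background=media_background,
            )
        else:
            field_seed = child_seed() if shared_field_seed is None else shared_field_seed
            truth = generate_spheroid_field(
                archetype, grid_shape, conc, field_seed,
                uptake_coefficient=uptake_coefficient,
                media_background=media_background,
            )
        well = SimulatedWell(well_id=well_id, role=role, concentration=conc, truth=truth)
        rng = np.random.default_rng(child_seed())
        for ch in channels:
            for tp in imaged_timepoints(ch):
                t = truth
                if ch == "pop" and tp == "post_activation":
                    t = truth.scaled_emission(bleach_factor)
                    well.truth_post[ch] = t
                for role_name in ("fluorescence", "nd_reference"):
                    well.frames.append(
                        render_channel_image(
                            t, optics, noise, role_name,
                            channel=ch, timepoint=tp, well_id=well_id, rng=rng,
                        )
                    )
        wells.append(well)

    return ExperimentBundle(
        wells=wells,
        calibration=calibration,
        optics=optics,
        noise=noise,
        concentrations=concentrations,
        bleach_factor=bleach_factor,
        seed=seed,
        grid_shape=grid_shape,
    )


def simulate_plate_reader(
    bundle: ExperimentBundle,
    seed: int,
    *,
    scale: float = 0.92,
    noise_cv: float = 0.03,
    channel: str = "dox",
) -> dict[str, float]:
    """Emulate bulk plate-reader readings of the same wells.

    The plate reader integrates total well fluorescence without spatial
    resolution; compact, optically dense aggregates self-attenuate, which is
    modelled as a multiplicative ``scale`` < 1 relative to the imaging
    platform's per-pixel mean scale, plus proportional measurement noise.
    Returns well_id -> reading for treatment wells.
    """
    rng = np.random.default_rng(seed)
    readings = {}
    for w in bundle.treatment_wells():
        truth = w.truth
        if channel == "pop":
            truth = w.truth_post.get(channel, truth)
        true_mean = bundle.expected_mean_signal(w, channel, "post_activation")
        readings[w.well_id] = float(
            scale * true_mean * (1.0 + rng.normal(0.0, noise_cv))
        )
    return readings
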