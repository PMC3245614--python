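"""Synthetic FISH scene generator.

Produces single-nucleus two-channel images (DAPI + chromosome paint) in 2D
or as confocal-style z-stacks, with chromosome territories placed at
controlled radial positions.  The generator provides ground truth — the true
normalized radial coordinate ``r`` of every territory — so the erosion-shell
and 3D-distance analyses can be validated end to end without real
microscopy data.

Radial coordinate convention
----------------------------
``r`` is the elliptical scale factor: a territory at radial coordinate
``r`` along unit direction ``u`` sits on the nucleus boundary shrunk by the
factor ``r`` (``r = 0`` nuclear center, ``r = 1`` periphery).  This gives
``r`` the same meaning along every direction of a (possibly perturbed)
elliptical nucleus.

Named radial laws are Beta distributions on the *area fraction*
``q = r**2`` (the fraction of nuclear area enclosed by the territory's
radial coordinate): because concentric shells of equal area are uniform in
``q``, a law on ``q`` reads directly in shell units — ``"peripheral"``
(Beta(8, 2) on q) concentrates territories in shells 1–2,
``"intermediate"`` (Beta(5, 5)) around shell 3, and ``"interior"``
(Beta(2, 8)) in shells 4–5.  A ``("custom", alpha, beta)`` law is a Beta
distribution on ``r`` itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "RADIAL_LAWS",
    "SceneConfig",
    "TerritoryGroundTruth",
    "NucleusImage",
    "radial_law_params",
    "sample_radial_law",
    "make_nucleus",
    "make_population",
    "make_population_pair",
    "elliptical_radius",
]

#: Named radial laws as Beta(alpha, beta) parameters on the enclosed-area
#: fraction q = r**2 in [0, 1].
RADIAL_LAWS = {
    "peripheral": (8.0, 2.0),
    "intermediate": (5.0, 5.0),
    "interior": (2.0, 8.0),
}

#: Orders of the low-frequency boundary perturbation (Fourier modes in the
#: in-plane polar angle).  Mode 1 is excluded: it mostly translates the
#: outline rather than deforming it.
_PERTURBATION_MODES = (2, 3, 4)


def radial_law_params(radial_law) -> tuple[str, float, float]:
    """Resolve a radial-law spec to ``(coordinate, alpha, beta)``.

    Named laws (``"peripheral"``, ``"intermediate"``, ``"interior"``) are
    Beta distributions on the enclosed-area fraction ``q = r**2``
    (``coordinate == "area"``); a ``("custom", alpha, beta)`` tuple/list or
    plain ``(alpha, beta)`` pair is a Beta distribution on ``r`` itself
    (``coordinate == "radius"``).
    """
    if isinstance(radial_law, str):
        try:
            alpha, beta = RADIAL_LAWS[radial_law]
        except KeyError:
            raise ConfigurationError(
                f"radial_law: unknown law {radial_law!r}; expected one of "
                f"{sorted(RADIAL_LAWS)} or ('custom', alpha, beta)"
            ) from None
        return "area", alpha, beta
    law = tuple(radial_law)
    if len(law) == 3 and law[0] == "custom":
        law = law[1:]
    if len(law) != 2:
        raise ConfigurationError(f"radial_law: cannot interpret {radial_law!r}")
    alpha, beta = float(law[0]), float(law[1])
    if alpha <= 0 or beta <= 0:
        raise ConfigurationError("radial_law: Beta parameters must be positive")
    return "radius", alpha, beta


def sample_radial_law(radial_law, rng: np.random.Generator, size=None):
    """Draw normalized radial coordinates r in [0, 1] from a radial law."""
    coordinate, alpha, beta = radial_law_params(radial_law)
    draw = rng.beta(alpha, beta, size)
    return np.sqrt(draw) if coordinate == "area" else draw


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic acquisition condition.

    Lengths are in micrometers; intensities in arbitrary (8-bit-like) units.
    ``image_shape`` is ``(rows, cols)`` for 2D or ``(planes, rows, cols)``
    for a z-stack; ``nucleus_axes`` are *semi*-axis lengths
    ``(major, minor[, axial])``.  ``nucleus_irregularity`` is the total
    relative amplitude of a low-order Fourier perturbation of the boundary
    radius (0 = perfect ellipse).  The same config plus the same seed always
    yields bit-identical output.
    """

    image_shape: tuple = (128, 128)
    pixel_size_xy: float = 0.2
    z_step: float | None = None
    nucleus_axes: tuple = (10.0, 7.0)
    nucleus_irregularity: float = 0.0
    dapi_level: float = 120.0
    probe_level: float = 150.0
    noise_sd: float = 5.0
    territory_radius: float = 2.5
    territories_per_nucleus: int = 2
    radial_law: object = "intermediate"
    blob_profile: str = "gaussian"
    n_nuclei: int = 50
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "image_shape", tuple(int(s) for s in self.image_shape))
        object.__setattr__(self, "nucleus_axes", tuple(float(a) for a in self.nucleus_axes))
        self.validate()

    # -- derived geometry -------------------------------------------------

    @property
    def ndim(self) -> int:
        return len(self.image_shape)

    @property
    def is_3d(self) -> bool:
        return self.ndim == 3

    @property
    def spacing(self) -> tuple:
        """Physical voxel size per array axis, μm: (z,)y,x order."""
        if self.is_3d:
            return (float(self.z_step), self.pixel_size_xy, self.pixel_size_xy)
        return (self.pixel_size_xy, self.pixel_size_xy)

    def axes_per_axis(self) -> np.ndarray:
        """Nucleus semi-axes reordered to match array axes ((z,)y,x), μm.

        The major axis is laid along the last (x) array axis, the minor
        along y, the axial (if 3D) along z.
        """
        major, minor = self.nucleus_axes[0], self.nucleus_axes[1]
        if self.is_3d:
            return np.array([self.nucleus_axes[2], minor, major])
        return np.array([minor, major])

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.ndim not in (2, 3):
            raise ConfigurationError("image_shape: must be 2D or 3D")
        if self.is_3d and (self.z_step is None or self.z_step <= 0):
            raise ConfigurationError("z_step: required and positive for 3D scenes")
        if self.pixel_size_xy <= 0:
            raise ConfigurationError("pixel_size_xy: must be positive")
        n_axes_expected = 3 if self.is_3d else 2
        if len(self.nucleus_axes) != n_axes_expected:
            raise ConfigurationError(
                f"nucleus_axes: expected {n_axes_expected} semi-axes for a "
                f"{self.ndim}D scene, got {len(self.nucleus_axes)}"
            )
        if any(a <= 0 for a in self.nucleus_axes):
            raise ConfigurationError("nucleus_axes: semi-axes must be positive")
        if self.nucleus_axes[0] < self.nucleus_axes[1]:
            raise ConfigurationError("nucleus_axes: major semi-axis must be >= minor")
        if self.nucleus_irregularity < 0:
            raise ConfigurationError("nucleus_irregularity: must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if self.dapi_level <= 0:
            raise ConfigurationError("dapi_level: must be positive")
        if self.probe_level <= 0:
            raise ConfigurationError("probe_level: must be positive")
        if self.territory_radius <= 0:
            raise ConfigurationError("territory_radius: must be positive")
        if self.territory_radius >= min(self.nucleus_axes):
            raise ConfigurationError(
                "territory_radius: territory does not fit inside the nucleus "
                "(radius >= smallest nucleus semi-axis)"
            )
        if self.territories_per_nucleus < 1:
            raise ConfigurationError("territories_per_nucleus: must be >= 1")
        if self.blob_profile not in ("gaussian", "disc"):
            raise ConfigurationError("blob_profile: must be 'gaussian' or 'disc'")
        if self.n_nuclei < 0:
            raise ConfigurationError("n_nuclei: must be >= 0")
        radial_law_params(self.radial_law)
        # nucleus (inflated by worst-case boundary perturbation) plus a
        # territory-radius margin must fit inside the image
        half_extent = (np.array(self.image_shape) - 1) / 2 * np.array(self.spacing)
        required = self.axes_per_axis() * (1 + self.nucleus_irregularity) + self.territory_radius
        for axis_name, req, half in zip("zyx"[-self.ndim:], required, half_extent):
            if req > half:
                raise ConfigurationError(
                    f"nucleus_axes: nucleus plus territory margin needs "
                    f"{req:.2f} μm along {axis_name} but the image half-extent "
                    f"is {half:.2f} μm"
                )


@dataclass(frozen=True)
class TerritoryGroundTruth:
    """True placement of one simulated territory."""

    territory_id: int
    center_um: tuple  # (z,)y,x order, μm from the array origin
    r: float  # normalized radial coordinate actually drawn


@dataclass
class NucleusImage:
    """One nucleus's DAPI and chromosome-paint rasters plus metadata.

    ``spacing`` is the physical size of one pixel/voxel per array axis in
    μm.  ``ground_truth`` is populated by the generator and absent
    (``None``) for images loaded from disk.  The generator additionally
    records the true nucleus geometry so ground-truth radial coordinates can
    be recomputed from territory centers.
    """

    dapi: np.ndarray
    probe: np.ndarray
    spacing: tuple
    nucleus_id: int = 0
    ground_truth: list | None = None
    nucleus_center_um: tuple | None = None
    nucleus_axes_um: tuple | None = None
    boundary_coeffs: np.ndarray | None = None

    def __post_init__(self):
        if self.dapi.shape != self.probe.shape:
            raise ConfigurationError("dapi and probe rasters must share a shape")
        if len(self.spacing) != self.dapi.ndim:
            raise ConfigurationError("spacing must have one entry per array axis")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing entries must be positive")
        if self.dapi.min() < 0 or self.probe.min() < 0:
            raise ConfigurationError("intensities must be non-negative")


def _boundary_factor(theta: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Relative boundary radius R(θ) of the perturbed outline.

    ``coeffs`` holds (amplitude, phase) per Fourier mode; amplitudes sum to
    the configured irregularity so R stays within [1 − irr, 1 + irr].
    """
    out = np.ones_like(theta, dtype=float)
    for (amp, phase), k in zip(coeffs, _PERTURBATION_MODES):
        out += amp * np.cos(k * theta + phase)
    return out


def _draw_boundary_coeffs(rng: np.random.Generator, irregularity: float) -> np.ndarray:
    n = len(_PERTURBATION_MODES)
    amps = irregularity * rng.dirichlet(np.ones(n))
    phases = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([amps, phases])


def elliptical_radius(point_um, center_um, axes_per_axis_um, boundary_coeffs=None) -> float:
    """Normalized radial coordinate r of a point inside a perturbed ellipse.

    ``axes_per_axis_um`` are the semi-axes in array-axis order ((z,)y,x).
    The in-plane polar angle (y, x components) drives the boundary
    perturbation, matching the generator.
    """
    v = (np.asarray(point_um, dtype=float) - np.asarray(center_um, dtype=float)) / np.asarray(
        axes_per_axis_um, dtype=float
    )
    rho = float(np.linalg.norm(v))
    if rho == 0:
        return 0.0
    theta = float(np.arctan2(v[-2], v[-1]))
    factor = 1.0
    if boundary_coeffs is not None:
        factor = float(_boundary_factor(np.array(theta), np.asarray(boundary_coeffs)))
    return rho / factor


def _unit_direction(rng: np.random.Generator, ndim: int) -> np.ndarray:
    if ndim == 2:
        psi = rng.uniform(0, 2 * np.pi)
        return np.array([np.sin(psi), np.cos(psi)])  # (y, x)
    v = rng.normal(size=3)  # isotropic on the sphere, (z, y, x)
    norm = np.linalg.norm(v)
    while norm < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
    return v / norm


def make_nucleus(config: SceneConfig, index: int = 0) -> NucleusImage:
    """Render one synthetic nucleus.

    Nuclei for distinct ``index`` values are statistically independent but
    jointly reproducible from ``config.seed``.  All territory placement
    randomness is drawn before the noise field, so raising ``noise_sd``
    perturbs the rasters without touching the ground truth.
    """
    if index < 0 or index >= config.n_nuclei:
        raise ConfigurationError(f"index {index} out of range for n_nuclei={config.n_nuclei}")
    rng = np.random.default_rng([abs(int(config.seed)), int(index)])
    spacing = np.array(config.spacing)
    shape = config.image_shape
    axes = config.axes_per_axis()
    center_um = (np.array(shape) - 1) / 2 * spacing

    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    rel = [(c - mu) / a for c, mu, a in zip(coords, center_um, axes)]
    rho = np.sqrt(sum(r * r for r in rel))
    theta = np.arctan2(rel[-2], rel[-1])

    coeffs = _draw_boundary_coeffs(rng, config.nucleus_irregularity)
    s = rho / _boundary_factor(theta, coeffs)  # elliptical radial coordinate field

    # smooth interior: full level inside, sub-pixel linear roll-off at the
    # rim.  (1 - s) * L approximates the spatial distance to the boundary
    # along the ray, with L the local boundary radius in μm.
    with np.errstate(invalid="ignore", divide="ignore"):
        local_radius = np.sqrt(sum((a * r) ** 2 for a, r in zip(axes, rel))) / rho
    local_radius = np.nan_to_num(local_radius, nan=float(min(axes)))
    local_radius *= _boundary_factor(theta, coeffs)
    edge_um = 0.5 * config.pixel_size_xy
    dapi = config.dapi_level * np.clip((1.0 - s) * local_radius / edge_um, 0.0, 1.0)

    probe = np.zeros(shape, dtype=float)
    ground_truth = []
    for t in range(config.territories_per_nucleus):
        r = float(sample_radial_law(config.radial_law, rng))
        u = _unit_direction(rng, config.ndim)
        theta_dir = float(np.arctan2(u[-2], u[-1]))
        factor = float(_boundary_factor(np.array(theta_dir), coeffs))
        pos_um = center_um + r * factor * axes * u
        if elliptical_radius(pos_um, center_um, axes, coeffs) > 1.0 + 1e-9:
            raise ConfigurationError(
                "radial_law: drew a territory center outside the nucleus "
                f"(r={r:.3f})"
            )
        d2 = sum((c - p) ** 2 for c, p in zip(coords, pos_um))
        if config.blob_profile == "gaussian":
            sigma = config.territory_radius / 2.0
            probe += config.probe_level * np.exp(-d2 / (2.0 * sigma**2))
        else:
            probe += config.probe_level * (d2 <= config.territory_radius**2)
        ground_truth.append(TerritoryGroundTruth(t, tuple(pos_um), r))

    if config.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, config.noise_sd, shape)
        probe = probe + rng.normal(0.0, config.noise_sd, shape)
    dapi = np.clip(dapi, 0.0, None).astype(np.float32)
    probe = np.clip(probe, 0.0, None).astype(np.float32)

    return NucleusImage(
        dapi=dapi,
        probe=probe,
        spacing=tuple(float(x) for x in spacing),
        nucleus_id=index,
        ground_truth=ground_truth,
        nucleus_center_um=tuple(float(x) for x in center_um),
        nucleus_axes_um=tuple(float(a) for a in axes),
        boundary_coeffs=coeffs,
    )


def make_population(config: SceneConfig) -> list[NucleusImage]:
    """Render the whole cohort described by ``config``."""
    if config.n_nuclei < 1:
        raise ConfigurationError("n_nuclei: cohort is empty")
    return [make_nucleus(config, i) for i in range(config.n_nuclei)]


def make_population_pair(
    config_a: SceneConfig, config_b: SceneConfig
) -> tuple[list[NucleusImage], list[NucleusImage]]:
    """Render two cohorts that differ only in radial law (and seed).

    This is the synthetic analogue of an experimental condition pair
    (e.g. proliferating vs quiescent cells, or untreated vs drug-treated),
    where acquisition geometry and optics are shared and only the territory
    positioning differs.
    """
    neutral_a = dataclasses.replace(config_a, radial_law="intermediate", seed=0)
    neutral_b = dataclasses.replace(config_b, radial_law="intermediate", seed=0)
    if neutral_a != neutral_b:
        raise ConfigurationError(
            "population pair: configs may differ only in radial_law and seed"
        )
    return make_population(config_a), make_population(config_b)
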