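"""Synthetic 3D cardiac-like phantoms and simulated low-resolution acquisitions.

The generator emulates the statistical structure the super-resolution
method assumes: isotropic volumes containing fine tubular structures
(vessel analogs, sub-voxel to a few voxels across), larger smooth
ellipsoidal compartments (chamber analogs), a gentle background gradient,
and mild Gaussian noise.  Four named contrast profiles stand in for the
four whole-heart MR sequences used clinically (REACT, non-contrast SSFP,
contrast-enhanced SSFP, and IR-prepped SSFP): they differ in background
level, vessel/background contrast, and compartment-shell brightness.

Low-resolution counterparts are produced by :func:`degrade` at factors
drawn uniformly from [2, 4] (including non-integer values), matching the
random-factor undersampling protocol the network is trained under.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .resample import resize_linear
from .shapes import downsampled_dims
from .volume import ScaleFactor, Volume3D, as_factor

__all__ = [
    "PhantomSpec",
    "CONTRAST_PROFILES",
    "generate_phantom",
    "degrade",
    "sample_scale",
    "make_training_pair",
    "make_corpus",
]


@dataclass(frozen=True)
class ContrastProfile:
    """Intensity recipe of one acquisition-sequence stand-in."""

    background: float
    tube_amp: float
    shell_amp: float
    interior_amp: float


#: Stand-ins for the four clinical whole-heart sequences.  "react" mimics a
#: non-contrast angiographic contrast (dark tissue, very bright vessels);
#: "ncssfp" a fat-saturated bright-blood scan with dark compartment shells;
#: "ssfp" a contrast-enhanced bright-blood scan; "irssfp" an IR-prepped scan
#: with suppressed background and a very bright blood pool.
CONTRAST_PROFILES: dict[str, ContrastProfile] = {
    "react": ContrastProfile(background=0.10, tube_amp=0.75, shell_amp=0.20, interior_amp=0.10),
    "ncssfp": ContrastProfile(background=0.30, tube_amp=0.55, shell_amp=-0.18, interior_amp=0.30),
    "ssfp": ContrastProfile(background=0.35, tube_amp=0.50, shell_amp=0.25, interior_amp=0.35),
    "irssfp": ContrastProfile(background=0.15, tube_amp=0.65, shell_amp=-0.10, interior_amp=0.45),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic high-resolution phantom.

    ``gradient_amp`` controls the smooth background intensity ramp; set it
    to 0 (together with ``n_tubes = n_blobs = 0`` and ``noise_sigma = 0``)
    for a strictly constant scene.
    """

    grid_size: tuple[int, int, int] = (64, 64, 64)
    n_tubes: int = 6
    tube_radius_range: tuple[float, float] = (0.8, 3.0)
    n_blobs: int = 3
    contrast_profile: str = "ssfp"
    noise_sigma: float = 0.01
    seed: int = 0
    gradient_amp: float = 0.04
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        if len(self.grid_size) != 3 or any(int(n) < 16 for n in self.grid_size):
            raise ValueError(f"grid_size components must be >= 16, got {self.grid_size}")
        lo, hi = self.tube_radius_range
        if lo < 0.5 or hi < lo:
            raise ValueError(
                f"tube_radius_range must satisfy 0.5 <= lo <= hi, got {self.tube_radius_range}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.n_tubes < 0 or self.n_blobs < 0:
            raise ValueError("structure counts must be nonnegative")
        if self.contrast_profile not in CONTRAST_PROFILES:
            raise ValueError(
                f"unknown contrast_profile {self.contrast_profile!r}; "
                f"choose from {sorted(CONTRAST_PROFILES)}"
            )


def _line_distance(p1: np.ndarray, d1: np.ndarray, p2: np.ndarray, d2: np.ndarray) -> float:
    """Minimum distance between two infinite lines (point + unit direction)."""
    cross = np.cross(d1, d2)
    norm = np.linalg.norm(cross)
    dp = p2 - p1
    if norm < 1e-12:  # parallel
        return float(np.linalg.norm(dp - np.dot(dp, d1) * d1))
    return float(abs(np.dot(dp, cross)) / norm)


def _place_tubes(
    spec: PhantomSpec, rng: np.random.Generator
) -> list[tuple[int, float, float, float]]:
    """Choose axis, perpendicular offsets, and radius for each tube.

    Tubes are full-span and axis-aligned (each parallel to a randomly
    chosen coordinate axis) and are rejection-sampled to stay separated by
    at least the sum of radii plus a 2-voxel guard, so connected-component
    labeling can recover the tube count in the noise-free case.
    """
    dims = np.asarray(spec.grid_size, dtype=float)
    placed: list[tuple[int, float, float, float]] = []
    axes_unit = np.eye(3)

    def try_place(radius: float) -> bool:
        for _attempt in range(400):
            axis = int(rng.integers(3))
            perp = [k for k in range(3) if k != axis]
            margin = radius + 2.0
            if any(dims[k] - 2 * margin <= 0 for k in perp):
                continue
            off = [float(rng.uniform(margin, dims[k] - 1 - margin)) for k in perp]
            point = np.zeros(3)
            point[perp[0]], point[perp[1]] = off
            ok = True
            for a2, o1, o2, r2 in placed:
                p2 = np.zeros(3)
                perp2 = [k for k in range(3) if k != a2]
                p2[perp2[0]], p2[perp2[1]] = o1, o2
                if _line_distance(point, axes_unit[axis], p2, axes_unit[a2]) < radius + r2 + 2.0:
                    ok = False
                    break
            if ok:
                placed.append((axis, off[0], off[1], radius))
                return True
        return False

    lo = spec.tube_radius_range[0]
    for _ in range(spec.n_tubes):
        radius = float(rng.uniform(*spec.tube_radius_range))
        done = try_place(radius)
        # crowded scenes: retry with progressively thinner tubes (still
        # within the requested radius range) before giving up
        shrink = 0
        while not done and shrink < 8 and radius > lo:
            radius = max(lo, radius * 0.7)
            done = try_place(radius)
            shrink += 1
        if not done:
            raise ValueError(
                f"grid {spec.grid_size} too small to host {spec.n_tubes} separated "
                f"tubes of radius up to {spec.tube_radius_range[1]} "
                "(separation constraint: center distance > r_i + r_j + 2 voxels)"
            )
    return placed


def generate_phantom(spec: PhantomSpec) -> Volume3D:
    """Render a high-resolution phantom; deterministic for a fixed seed.

    Tube cross-sections use a one-voxel linear edge ramp so that the set of
    voxels above half the tube amplitude matches the analytic cylinder
    cross-section (voxel centers within the tube radius).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    prof = CONTRAST_PROFILES[spec.contrast_profile]
    nx, ny, nz = (int(n) for n in spec.grid_size)
    vol = np.full((nx, ny, nz), prof.background, dtype=np.float64)

    coords = [np.arange(n, dtype=np.float64) for n in (nx, ny, nz)]

    if spec.gradient_amp > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        norm = [(c / max(len(c) - 1, 1)) - 0.5 for c in coords]
        ramp = (
            direction[0] * norm[0][:, None, None]
            + direction[1] * norm[1][None, :, None]
            + direction[2] * norm[2][None, None, :]
        )
        vol += spec.gradient_amp * ramp

    dims = np.array([nx, ny, nz], dtype=float)
    for _ in range(spec.n_blobs):
        center = rng.uniform(0.3, 0.7, size=3) * (dims - 1)
        semi = rng.uniform(dims / 10.0, dims / 5.0)
        rho = np.sqrt(
            ((coords[0][:, None, None] - center[0]) / semi[0]) ** 2
            + ((coords[1][None, :, None] - center[1]) / semi[1]) ** 2
            + ((coords[2][None, None, :] - center[2]) / semi[2]) ** 2
        )
        interior = 1.0 / (1.0 + np.exp((rho - 1.0) / 0.05))
        shell = np.exp(-0.5 * ((rho - 1.0) / 0.08) ** 2)
        vol += prof.interior_amp * interior - prof.background * interior
        vol += prof.shell_amp * shell

    for axis, o1, o2, radius in _place_tubes(spec, rng):
        perp = [k for k in range(3) if k != axis]
        g1 = coords[perp[0]]
        g2 = coords[perp[1]]
        d = np.sqrt((g1[:, None] - o1) ** 2 + (g2[None, :] - o2) ** 2)
        ramp2d = np.clip(radius + 0.5 - d, 0.0, 1.0)
        footprint = np.ones((nx, ny, nz))
        shape = [1, 1, 1]
        shape[perp[0]], shape[perp[1]] = ramp2d.shape
        footprint = np.broadcast_to(ramp2d.reshape(shape), (nx, ny, nz))
        vol = vol + prof.tube_amp * footprint

    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)

    return Volume3D(vol.astype(np.float32), spacing=spec.spacing).normalize()


def degrade(
    hr: Volume3D, s: "ScaleFactor | float", method: str = "trilinear"
) -> Volume3D:
    """Simulate a low-resolution acquisition of ``hr`` at factor ``s``.

    Output dimensions are ``floor(N / s)`` per axis and spacing is scaled
    by ``s``.  ``method="trilinear"`` resamples in image space (preserves
    constant fields exactly); ``method="kspace_truncation"`` crops the
    central band of the shifted spectrum, i.e. an ideal low-pass
    acquisition with no content above the low-resolution Nyquist band.
    """
    sf = as_factor(s)
    out_dims = downsampled_dims(hr.shape, sf)
    if any(m < 8 for m in out_dims):
        raise ValueError(
            f"degrading {hr.shape} by {sf} gives {out_dims}; every output "
            "dimension must be >= 8"
        )
    spacing = tuple(sp * sf for sp in hr.spacing)
    if method == "trilinear":
        data = resize_linear(hr.data, out_dims)
    elif method in ("kspace_truncation", "kspace"):
        spec = np.fft.fftshift(np.fft.fftn(hr.data.astype(np.float64), norm="ortho"))
        sl = []
        for n, m in zip(hr.shape, out_dims):
            start = n // 2 - m // 2
            sl.append(slice(start, start + m))
        cropped = spec[tuple(sl)]
        scale = np.sqrt(np.prod(out_dims) / np.prod(hr.shape))
        data = np.real(np.fft.ifftn(np.fft.ifftshift(cropped), norm="ortho")) * scale
        data = data.astype(hr.data.dtype)
    else:
        raise ValueError(f"unknown degradation method {method!r}")
    return Volume3D(data, spacing=spacing)


def sample_scale(
    lo: float = 2.0, hi: float = 4.0, rng: np.random.Generator | None = None
) -> ScaleFactor:
    """Draw a super-resolution factor uniformly from [lo, hi)."""
    if not (1 <= lo < hi):
        raise ValueError(f"need 1 <= lo < hi, got lo={lo}, hi={hi}")
    rng = np.random.default_rng() if rng is None else rng
    return ScaleFactor(float(rng.uniform(lo, hi)))


def make_training_pair(
    spec: PhantomSpec,
    rng: np.random.Generator,
    scale_range: tuple[float, float] = (2.0, 4.0),
    method: str = "trilinear",
) -> tuple[Volume3D, Volume3D, ScaleFactor]:
    """Compose phantom generation, factor sampling, and degradation.

    Returns ``(lr, hr, s)``; reproducible from ``(spec.seed, rng state)``.
    """
    hr = generate_phantom(spec)
    s = sample_scale(*scale_range, rng=rng)
    lr = degrade(hr, s, method=method)
    return lr, hr, s


def make_corpus(
    n: int,
    grid_size: tuple[int, int, int] = (32, 32, 32),
    profiles: tuple[str, ...] = ("react", "ncssfp", "ssfp", "irssfp"),
    noise_sigma: float = 0.01,
    base_seed: int = 0,
    **spec_kwargs,
) -> list[tuple[str, str, Volume3D]]:
    """Generate ``n`` phantoms cycling through the contrast profiles.

    Returns ``(volume_id, contrast_profile, volume)`` triples; each volume
    gets its own seed derived from ``base_seed`` so corpora are fully
    reproducible and regenerable.
    """
    out = []
    for i in range(n):
        profile = profiles[i % len(profiles)]
        spec = PhantomSpec(
            grid_size=grid_size,
            contrast_profile=profile,
            noise_sigma=noise_sigma,
            seed=int(base_seed) + i,
            **spec_kwargs,
        )
        out.append((f"phantom_{i:03d}", profile, generate_phantom(spec)))
    return out
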