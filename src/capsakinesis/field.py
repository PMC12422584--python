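"""Chemo-effector concentration field around the prey.

The prey exudes a chemokinesis-inducing chemical (modelled on serum
albumin) whose dispersal is standard isotropic diffusion with constant
diffusivity in two dimensions — cells crawl on a surface, so the field is
depth-averaged. Concentrations are in dose units (mg/ml), positions in µm,
diffusivity in µm²/s; a source rate is therefore expressed in
concentration·µm²/s (mass per unit depth per second).

Two solvers are provided:

* :class:`DiffusionField` — explicit finite differences on a square
  Cartesian grid (Dirichlet-zero "absorbing" edges mimicking an open bath
  far from the arena, or zero-flux "reflecting" edges for conservation
  tests). Handles arbitrary source layouts, including the depleted-prey
  burst scenario.
* :class:`RadialDiffusionField` — a radially symmetric fast path for a
  single central prey, finite volumes on annuli.

The exudation rate grows with the number of predator cells attached to the
prey surface (:class:`SourceModel`); the default coupling is linear:
``rate = base_rate * (1 + n_attached)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SourceModel", "DiffusionField", "RadialDiffusionField",
           "depleted_prey_profile", "step_field", "gaussian_plume"]


@dataclass(frozen=True)
class SourceModel:
    """Exudation rate of the prey as a function of attached predators.

    ``rate(n) = base_rate + attachment_coupling * n``; the default coupling
    equals ``base_rate``, i.e. ``rate = base_rate * (1 + n_attached)``.
    """

    base_rate: float
    attachment_coupling: float | None = None

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        if self.attachment_coupling is not None and self.attachment_coupling < 0:
            raise ValueError("attachment_coupling must be non-negative")

    def rate(self, n_attached: int) -> float:
        coupling = self.base_rate if self.attachment_coupling is None \
            else self.attachment_coupling
        return self.base_rate + coupling * n_attached


def gaussian_plume(r2, mass: float, diffusivity: float, age: float):
    """2-D Green's function: concentration at squared distance ``r2`` from
    an instantaneous point release of ``mass`` after ``age`` seconds."""
    return mass / (4.0 * np.pi * diffusivity * age) * np.exp(-r2 / (4.0 * diffusivity * age))


@dataclass
class DiffusionField:
    """Explicit 2-D diffusion on a square grid.

    The domain is ``[origin, origin + extent]²`` with ``n × n`` cells;
    concentrations live at cell centres. ``boundary`` is ``"absorbing"``
    (Dirichlet 0 just outside the edge) or ``"reflecting"`` (zero flux).
    """

    extent: float
    n: int
    diffusivity: float
    boundary: str = "absorbing"
    origin: tuple = (0.0, 0.0)
    source_center: tuple | None = None
    source_radius: float = 0.0
    C: np.ndarray = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.extent <= 0 or self.n < 3:
            raise ValueError("extent must be positive and n >= 3")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.boundary not in ("absorbing", "reflecting"):
            raise ValueError("boundary must be 'absorbing' or 'reflecting'")
        if self.C is None:
            self.C = np.zeros((self.n, self.n))
        self._source_mask = None

    @property
    def dx(self) -> float:
        return self.extent / self.n

    @property
    def stability_dt(self) -> float:
        """Largest stable explicit time step, dx²/(4D)."""
        return self.dx**2 / (4.0 * self.diffusivity)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        c = (np.arange(self.n) + 0.5) * self.dx
        return self.origin[0] + c, self.origin[1] + c

    def _mask_for(self, center, radius) -> np.ndarray:
        xs, ys = self.cell_centers()
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
        mask = r2 <= max(radius, self.dx / 2.0) ** 2
        if not mask.any():
            mask = r2 == r2.min()
        return mask

    def deposit(self, mass: float, center, radius: float = 0.0) -> None:
        """Add ``mass`` (concentration·µm²) uniformly over a disk of cells."""
        mask = self._mask_for(center, radius)
        self.C[mask] += mass / (mask.sum() * self.dx**2)

    def step(self, dt: float, rate: float = 0.0) -> None:
        """Advance one explicit step; raises if ``dt`` violates stability."""
        if dt > self.stability_dt * (1 + 1e-12):
            raise ValueError(
                f"dt={dt:g} exceeds the explicit stability bound "
                f"{self.stability_dt:g} s; use advance() for substepping")
        mode = "constant" if self.boundary == "absorbing" else "edge"
        P = np.pad(self.C, 1, mode=mode)
        lap = (P[2:, 1:-1] + P[:-2, 1:-1] + P[1:-1, 2:] + P[1:-1, :-2]
               - 4.0 * self.C) / self.dx**2
        self.C += dt * self.diffusivity * lap
        if rate > 0.0:
            if self.source_center is None:
                raise ValueError("field has no source_center for injection")
            if self._source_mask is None:
                self._source_mask = self._mask_for(self.source_center,
                                                   self.source_radius)
            self.C[self._source_mask] += rate * dt / (self._source_mask.sum() * self.dx**2)
        self.time += dt

    def advance(self, duration: float, rate: float = 0.0,
                safety: float = 0.9) -> None:
        """Advance by ``duration`` seconds using stable substeps."""
        if duration <= 0:
            return
        n_sub = max(1, int(np.ceil(duration / (safety * self.stability_dt))))
        dt = duration / n_sub
        for _ in range(n_sub):
            self.step(dt, rate)

    def concentration_at(self, x, y):
        """Bilinear interpolation of the field; clamped outside the domain
        (zero beyond an absorbing edge's ghost cells, edge value beyond a
        reflecting one). Always non-negative input in, non-negative out."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        gx = (x - self.origin[0]) / self.dx - 0.5
        gy = (y - self.origin[1]) / self.dx - 0.5
        gx = np.clip(gx, 0.0, self.n - 1.0)
        gy = np.clip(gy, 0.0, self.n - 1.0)
        i0 = np.clip(np.floor(gx).astype(int), 0, self.n - 2)
        j0 = np.clip(np.floor(gy).astype(int), 0, self.n - 2)
        fx = gx - i0
        fy = gy - j0
        c = (self.C[i0, j0] * (1 - fx) * (1 - fy)
             + self.C[i0 + 1, j0] * fx * (1 - fy)
             + self.C[i0, j0 + 1] * (1 - fx) * fy
             + self.C[i0 + 1, j0 + 1] * fx * fy)
        return c if c.shape else float(c)

    def total_mass(self) -> float:
        """Integrated concentration (concentration·µm²)."""
        return float(self.C.sum() * self.dx**2)

    def add_gaussian(self, center, mass: float, age: float) -> None:
        """Superpose the plume of an instantaneous point release of ``mass``
        that occurred ``age`` seconds ago. Very young plumes (narrower than
        a grid cell) degrade gracefully to a single-cell deposit."""
        if mass < 0:
            raise ValueError("mass must be non-negative")
        if mass == 0:
            return
        sigma2 = 2.0 * self.diffusivity * age
        if sigma2 < self.dx**2:
            self.deposit(mass, center)
            return
        xs, ys = self.cell_centers()
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
        self.C += gaussian_plume(r2, mass, self.diffusivity, age)


@dataclass
class RadialDiffusionField:
    """Radially symmetric diffusion from a central source (fast path).

    Finite volumes on annuli over ``[0, radius]``; zero flux through r = 0,
    absorbing or reflecting at the outer rim. Useful as the symmetric
    single-prey solver and as a cross-check of the Cartesian grid.
    """

    radius: float
    n: int
    diffusivity: float
    boundary: str = "absorbing"
    source_radius: float = 0.0
    C: np.ndarray = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.n < 3:
            raise ValueError("radius must be positive and n >= 3")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.boundary not in ("absorbing", "reflecting"):
            raise ValueError("boundary must be 'absorbing' or 'reflecting'")
        if self.C is None:
            self.C = np.zeros(self.n)

    @property
    def dr(self) -> float:
        return self.radius / self.n

    @property
    def stability_dt(self) -> float:
        return self.dr**2 / (4.0 * self.diffusivity)

    def cell_centers(self) -> np.ndarray:
        return (np.arange(self.n) + 0.5) * self.dr

    def step(self, dt: float, rate: float = 0.0) -> None:
        if dt > self.stability_dt * (1 + 1e-12):
            raise ValueError(f"dt={dt:g} exceeds stability bound "
                             f"{self.stability_dt:g} s")
        r = self.cell_centers()
        r_plus = r + self.dr / 2.0
        r_minus = r - self.dr / 2.0
        Cp = np.empty(self.n + 2)
        Cp[1:-1] = self.C
        Cp[0] = self.C[0]  # zero flux at the origin
        Cp[-1] = 0.0 if self.boundary == "absorbing" else self.C[-1]
        flux_out = r_plus * (Cp[2:] - Cp[1:-1]) / self.dr
        flux_in = r_minus * (Cp[1:-1] - Cp[:-2]) / self.dr
        flux_in[0] = 0.0
        self.C += dt * self.diffusivity * (flux_out - flux_in) / (r * self.dr)
        if rate > 0.0:
            rs = max(self.source_radius, self.dr)
            mask = r <= rs
            area = float(np.sum(2.0 * np.pi * r[mask] * self.dr))
            self.C[mask] += rate * dt / area
        self.time += dt

    def advance(self, duration: float, rate: float = 0.0,
                safety: float = 0.9) -> None:
        if duration <= 0:
            return
        n_sub = max(1, int(np.ceil(duration / (safety * self.stability_dt))))
        dt = duration / n_sub
        for _ in range(n_sub):
            self.step(dt, rate)

    def concentration_at(self, r):
        r = np.asarray(r, dtype=float)
        g = np.clip(r / self.dr - 0.5, 0.0, self.n - 1.0)
        i0 = np.clip(np.floor(g).astype(int), 0, self.n - 2)
        f = g - i0
        c = self.C[i0] * (1 - f) + self.C[i0 + 1] * f
        return c if c.shape else float(c)

    def total_mass(self) -> float:
        r = self.cell_centers()
        return float(np.sum(self.C * 2.0 * np.pi * r * self.dr))


def step_field(state: DiffusionField, source: SourceModel,
               n_attached: int, dt: float) -> DiffusionField:
    """Advance the field by ``dt`` with attachment-coupled injection."""
    state.advance(dt, rate=source.rate(n_attached))
    return state


def depleted_prey_profile(centers, burst_mass: float, age: float,
                          diffusivity: float, extent: float, n: int,
                          origin=(0.0, 0.0), boundary: str = "absorbing",
                          source_center=None, source_radius: float = 0.0) -> DiffusionField:
    """Initial field for the depleted-prey scenario.

    Several recently devoured prey, each at one of ``centers``, released a
    final burst of ``burst_mass`` (concentration·µm²) ``age`` seconds before
    the simulation starts; the bursts superpose as Gaussian plumes on top of
    an otherwise empty field whose live source is configured separately.
    """
    if len(centers) < 1:
        raise ValueError("need at least one depleted-prey center")
    if burst_mass < 0:
        raise ValueError("burst_mass must be non-negative")
    if age < 0:
        raise ValueError("age must be non-negative")
    fld = DiffusionField(extent=extent, n=n, diffusivity=diffusivity,
                         boundary=boundary, origin=origin,
                         source_center=source_center, source_radius=source_radius)
    for c in centers:
        if age == 0:
            fld.deposit(burst_mass, c)
        else:
            fld.add_gaussian(c, burst_mass, age)
    return fld
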