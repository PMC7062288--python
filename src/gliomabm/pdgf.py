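"""PDGF concentration field on the hexagonal lattice.

Each simulation step the field receives point-source secretion from
infected cells and point-sink consumption from all active cells (at their
nearest hex nodes), then undergoes first-order decay followed by diffusion.

Diffusion uses the standard second-order hexagonal stencil

    lap C_i = 2 / (3 h^2) * sum_{j in N(i)} (C_j - C_i)

with no-flux boundaries (missing neighbors simply do not exchange mass),
explicitly sub-stepped to satisfy the stability bound
``dt_sub <= 0.9 * 3 h^2 / (12 D)``.  Decay is applied in exponential form
``C <- C exp(-r_d dt)`` for step-size robustness.

Units: concentrations in ng/mL, rates are stored in the per-day units of
the parameter table and converted to hours internally.
"""

from __future__ import annotations

import numpy as np

from .tissue import TissueDomain, OutsideTissueError

H_PER_DAY = 24.0
CM2_TO_UM2 = 1.0e8


class PDGFField:
    """Concentration per hex node plus the four field operators.

    Parameters
    ----------
    domain : TissueDomain
    D_p : diffusion coefficient, cm^2/day
    r_d : decay rate, 1/day
    r_s : secretion rate per infected cell, ng/mL per cell per day
    r_c : consumption rate per cell, expressed as a fraction of ``r_s``
    """

    def __init__(self, domain: TissueDomain, D_p: float, r_d: float,
                 r_s: float, r_c: float):
        self.domain = domain
        self.D_p = float(D_p)
        self.r_d = float(r_d)
        self.r_s = float(r_s)
        self.r_c = float(r_c)
        self.conc = np.zeros(domain.n_hex, dtype=np.float64)
        self._mask = domain.hex_in_tissue.ravel()
        nbr = domain.hex_neighbors
        self._nbr_ext = np.where(nbr >= 0, nbr, domain.n_hex)
        self._degree = (nbr >= 0).sum(axis=1).astype(np.float64)
        h = domain.hex_spacing
        self._lap_coeff = 2.0 / (3.0 * h * h)  # 1/μm^2
        D_um2_h = self.D_p * CM2_TO_UM2 / H_PER_DAY
        self._alpha_per_h = D_um2_h * self._lap_coeff  # 1/h
        self._dt_sub_max = np.inf if D_um2_h == 0 else 0.9 * (3.0 * h * h) / (12.0 * D_um2_h)

    # ------------------------------------------------------------ operators
    def deposit_initial_bolus(self, p_0: float, site, radius: float) -> None:
        """Set every in-tissue hex node within ``radius`` μm of ``site`` to p_0."""
        import warnings

        x0, y0 = site
        if not bool(self.domain.in_tissue(x0, y0)[0]):
            raise OutsideTissueError("bolus site outside tissue")
        if not (100.0 <= p_0 <= 600.0):
            warnings.warn("initial PDGF outside the 100-600 ng/mL search range")
        d2 = (self.domain.hex_x.ravel() - x0) ** 2 + (self.domain.hex_y.ravel() - y0) ** 2
        sel = (d2 <= radius * radius) & self._mask
        if not sel.any():
            sel = np.zeros(self.domain.n_hex, dtype=bool)
            sel[self.domain.nearest_hex_node(x0, y0)] = True
        self.conc[sel] = p_0

    def secrete(self, infected_hex_idx: np.ndarray, dt: float) -> None:
        """Each infected cell adds ``r_s * dt`` to its nearest hex node."""
        if len(infected_hex_idx) == 0:
            return
        amount = self.r_s * dt / H_PER_DAY
        np.add.at(self.conc, infected_hex_idx, amount)

    def consume(self, active_hex_idx: np.ndarray, dt: float) -> None:
        """Each active cell removes up to ``r_c * r_s * dt``; nodes never go negative."""
        if len(active_hex_idx) == 0 or self.r_c == 0.0:
            return
        counts = np.bincount(active_hex_idx, minlength=self.domain.n_hex)
        demand = counts * (self.r_c * self.r_s * dt / H_PER_DAY)
        np.minimum(demand, self.conc, out=demand)
        self.conc -= demand

    def decay(self, dt: float) -> None:
        if self.r_d == 0.0:
            return
        self.conc *= np.exp(-self.r_d * dt / H_PER_DAY)

    def diffuse(self, dt: float) -> None:
        if self.D_p == 0.0:
            return
        n_sub = max(int(np.ceil(dt / self._dt_sub_max)), 1)
        dt_sub = dt / n_sub
        coeff = self._alpha_per_h * dt_sub
        conc_ext = np.empty(self.domain.n_hex + 1, dtype=np.float64)
        conc_ext[-1] = 0.0
        for _ in range(n_sub):
            conc_ext[:-1] = self.conc
            nbr_sum = conc_ext[self._nbr_ext].sum(axis=1)
            self.conc += coeff * (nbr_sum - self._degree * self.conc)

    # ---------------------------------------------------------- diagnostics
    def total_mass(self) -> float:
        return float(self.conc[self._mask].sum())

    def to_dataframe(self):
        import pandas as pd

        ids = np.nonzero(self._mask)[0]
        return pd.DataFrame(
            {
                "node_id": ids,
                "x_um": self.domain.hex_x.ravel()[ids],
                "y_um": self.domain.hex_y.ravel()[ids],
                "conc_ng_ml": self.conc[ids],
            }
        )

    def write_png(self, path) -> None:
        """Rasterized grayscale snapshot for quick visual inspection."""
        import imageio.v3 as iio

        grid = self.conc.reshape(self.domain.hex_nrows, self.domain.hex_ncols)
        peak = grid.max()
        img = np.zeros_like(grid) if peak == 0 else grid / peak
        iio.imwrite(path, (img * 255).astype(np.uint8))
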