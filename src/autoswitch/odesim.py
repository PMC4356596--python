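"""Mass-action ODE integration of the expanded network and its observables.

State variables are continuous copy numbers per cell.  Each reaction
contributes a flux equal to its effective rate constant times the product of
its reactant amounts (squared when a reactant appears twice); the analytic
Jacobian is assembled sparsely, which keeps the stiff BDF integrator fast on
the full network (173 species, 6,581 reactions).

The observables mirror the model's readouts: the fraction of AMBRA1
phosphorylated by ULK1 (autophagy proxy), the fraction of EIF4EBP1
phosphorylated by MTORC1 (translation proxy), and per-site phosphorylation
fractions for the regulatory sites of ULK1 and RPTOR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .network import ReactionNetwork


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid time reached."""

    def __init__(self, message: str, t_last: Optional[float] = None):
        super().__init__(message)
        self.t_last = t_last


# ---------------------------------------------------------------------------
# Drift (slow source/sink used by the bifurcation sweeps)
# ---------------------------------------------------------------------------


@dataclass
class Drift:
    """Very slow zeroth-order source or saturating first-order sink on one
    species (the free monomer of the drifted input).

    The sink removes the species at rate ``k_eps * y / (y + saturation)``:
    effectively a constant-rate removal while the free pool is populated that
    smoothly switches off as the pool empties, so amounts stay non-negative.
    """

    species_index: int
    k_eps: float  # copies/cell/s
    mode: str = "source"  # "source" | "sink"
    saturation: float = 10.0  # copies/cell, sink half-saturation

    def __post_init__(self) -> None:
        if self.mode not in ("source", "sink"):
            raise ValueError(f"unknown drift mode {self.mode!r}")
        if self.k_eps <= 0:
            raise ValueError("drift rate must be positive")


# ---------------------------------------------------------------------------
# Mass-action right-hand side
# ---------------------------------------------------------------------------


class MassActionSystem:
    """Vectorized RHS and Jacobian for one network + parameter set."""

    def __init__(self, network: ReactionNetwork, params: dict[str, float],
                 drift: Optional[Drift] = None):
        self.network = network
        self.params = dict(params)
        self.drift = drift
        n_s, n_r = network.n_species, network.n_reactions
        self.n_species = n_s

        k = network.rate_values(self.params)
        uni, bi = [], []
        for r, rx in enumerate(network.reactions):
            (uni if len(rx.reactants) == 1 else bi).append(r)
        self._uni = np.array(uni, dtype=np.intp)
        self._bi = np.array(bi, dtype=np.intp)
        self._uni_i = np.array([network.reactions[r].reactants[0] for r in uni],
                               dtype=np.intp)
        self._bi_i = np.array([network.reactions[r].reactants[0] for r in bi],
                              dtype=np.intp)
        self._bi_j = np.array([network.reactions[r].reactants[1] for r in bi],
                              dtype=np.intp)
        self._k_uni = k[self._uni]
        self._k_bi = k[self._bi]

        rows, cols, vals = [], [], []
        for r, rx in enumerate(network.reactions):
            for i in rx.reactants:
                rows.append(i); cols.append(r); vals.append(-1.0)
            for i in rx.products:
                rows.append(i); cols.append(r); vals.append(1.0)
        self.stoich = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_s, n_r)
        )
        # Fixed sparsity pattern for the reaction-by-species flux Jacobian.
        self._jac_rows = np.concatenate([self._uni, self._bi, self._bi])
        self._jac_cols = np.concatenate([self._uni_i, self._bi_i, self._bi_j])
        self._flux = np.empty(n_r)

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        f = self._flux
        f[self._uni] = self._k_uni * y[self._uni_i]
        f[self._bi] = self._k_bi * y[self._bi_i] * y[self._bi_j]
        return f

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.stoich @ self.fluxes(y)
        d = self.drift
        if d is not None:
            if d.mode == "source":
                dy[d.species_index] += d.k_eps
            else:
                yi = y[d.species_index]
                dy[d.species_index] -= d.k_eps * yi / (yi + d.saturation)
        return dy

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        data = np.concatenate([
            self._k_uni,
            self._k_bi * y[self._bi_j],
            self._k_bi * y[self._bi_i],
        ])
        dflux = sparse.coo_matrix(
            (data, (self._jac_rows, self._jac_cols)),
            shape=(len(self.network.reactions), self.n_species),
        ).tocsr()
        J = (self.stoich @ dflux).toarray()
        d = self.drift
        if d is not None and d.mode == "sink":
            yi = y[d.species_index]
            J[d.species_index, d.species_index] -= (
                d.k_eps * d.saturation / (yi + d.saturation) ** 2
            )
        return J


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


class ObservableSet:
    """Phosphorylation-fraction observables over network species.

    Each observable is a weighted species sum divided by the total copy
    number of the carrier molecule.  For the three-state lumped RPTOR site
    S855_S859 the singly phosphorylated form counts half and the doubly
    phosphorylated form counts fully, i.e. the fraction of the two lumped
    residues that are phosphorylated.
    """

    SITE_WEIGHTS: dict[str, tuple[str, str, dict[str, float]]] = {
        "frac_AMBRA1_P": ("AMBRA1", "ST", {"P": 1.0}),
        "frac_EIF4EBP1_P": ("EIF4EBP1", "S65_T70", {"P": 1.0}),
        "frac_ULK1_S317_P": ("ULK1", "S317", {"P": 1.0}),
        "frac_ULK1_S758_P": ("ULK1", "S758", {"P": 1.0}),
        "frac_ULK1_S778_P": ("ULK1", "S778", {"P": 1.0}),
        "frac_RPTOR_S792_P": ("RPTOR", "S792", {"P": 1.0}),
        "frac_RPTOR_S855_S859_P": ("RPTOR", "S855_S859", {"P": 0.5, "PP": 1.0}),
        "frac_AMPK_ST_P": ("AMPK", "ST", {"P": 1.0}),
    }

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.names = []
        num_rows, den_rows = [], []
        for name, (mtype, site, weights) in self.SITE_WEIGHTS.items():
            num = np.zeros(network.n_species)
            den = np.zeros(network.n_species)
            relevant = False
            for j, sp in enumerate(network.species):
                for mol in sp.molecules:
                    if mol.type == mtype and site in mol.sites:
                        relevant = True
                        den[j] += 1.0
                        num[j] += weights.get(mol.sites[site], 0.0)
            if relevant:
                self.names.append(name)
                num_rows.append(num)
                den_rows.append(den)
        self._num = np.array(num_rows)
        self._den = np.array(den_rows)

    def evaluate(self, y: np.ndarray) -> np.ndarray:
        """Observable matrix for states ``y`` of shape (n_t, n_species)."""
        num = self._num @ y.T
        den = self._den @ y.T
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(den > 0, num / den, 0.0)
        return frac

    def frame(self, t: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        frac = self.evaluate(y)
        df = pd.DataFrame({"time": t})
        for i, name in enumerate(self.names):
            df[name] = frac[i]
        return df


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time series of species copy numbers plus derived observables."""

    t: np.ndarray          # (n_t,), seconds
    y: np.ndarray          # (n_t, n_species), copies/cell
    network: ReactionNetwork

    def __post_init__(self) -> None:
        self._obs: Optional[ObservableSet] = None

    @property
    def observable_set(self) -> ObservableSet:
        if self._obs is None:
            self._obs = ObservableSet(self.network)
        return self._obs

    def observables(self) -> pd.DataFrame:
        return self.observable_set.frame(self.t, self.y)

    def observable(self, name: str) -> np.ndarray:
        idx = self.observable_set.names.index(name)
        return self.observable_set.evaluate(self.y)[idx]

    def final_state(self) -> np.ndarray:
        return self.y[-1].copy()

    def molecule_totals(self) -> pd.DataFrame:
        types, mat = self.network.molecule_count_matrix()
        return pd.DataFrame((mat @ self.y.T).T, columns=types, index=self.t)

    def conservation_error(self) -> float:
        """Largest relative drift of any molecule-type total (0 = exact)."""
        totals = self.molecule_totals().to_numpy()
        ref = totals[0]
        mask = ref > 0
        if not mask.any():
            return 0.0
        return float(np.max(np.abs(totals[:, mask] - ref[mask]) / ref[mask]))


# ---------------------------------------------------------------------------
# Simulation drivers
# ---------------------------------------------------------------------------


def simulate(network: ReactionNetwork, params: dict[str, float],
             duration: float,
             y0: Optional[np.ndarray] = None,
             n_points: int = 1000,
             rtol: float = 1e-8,
             atol: float = 1e-6,
             method: str = "BDF",
             drift: Optional[Drift] = None,
             t_eval: Optional[np.ndarray] = None,
             events: Optional[Sequence[Callable]] = None) -> Trajectory:
    """Integrate the network ODEs for ``duration`` seconds.

    Starts from the seed amounts in ``params`` unless ``y0`` is given.
    Output is sampled on ``n_points`` evenly spaced times (or ``t_eval``).
    Raises :class:`SimulationError` with the last valid time on solver
    failure.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    sys_ = MassActionSystem(network, params, drift=drift)
    if y0 is None:
        y0 = network.initial_state(params)
    if t_eval is None:
        t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(sys_.rhs, (0.0, duration), y0, method=method,
                    jac=sys_.jac, rtol=rtol, atol=atol, t_eval=t_eval,
                    events=events)
    if not sol.success and sol.status < 0:
        t_last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(f"integration failed: {sol.message}", t_last=t_last)
    return Trajectory(sol.t, sol.y.T, network)


def find_steady_state(network: ReactionNetwork, params: dict[str, float],
                      y0: Optional[np.ndarray] = None,
                      tol: float = 1e-10,
                      t_cap: float = 1e7,
                      rtol: float = 1e-8,
                      atol: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Relax to a steady state by integrating in growing chunks.

    Convergence criterion: ``max |dy/dt| / max(1, |y|) < tol``.  Returns the
    final state and a convergence flag (False when the time cap is hit, e.g.
    on a limit cycle).
    """
    sys_ = MassActionSystem(network, params)
    y = network.initial_state(params) if y0 is None else np.asarray(y0, float).copy()

    def residual(y: np.ndarray) -> float:
        dy = sys_.rhs(0.0, y)
        return float(np.max(np.abs(dy) / np.maximum(1.0, np.abs(y))))

    if residual(y) < tol:
        return y, True
    t_done, chunk = 0.0, 1e3
    while t_done < t_cap:
        chunk = min(chunk, t_cap - t_done)
        sol = solve_ivp(sys_.rhs, (0.0, chunk), y, method="BDF", jac=sys_.jac,
                        rtol=rtol, atol=atol, t_eval=[chunk])
        if not sol.success:
            raise SimulationError(
                f"steady-state relaxation failed: {sol.message}", t_last=t_done)
        y = sol.y[:, -1]
        t_done += chunk
        if residual(y) < tol:
            return y, True
        chunk *= 4.0
    return y, False


def apply_stress(network: ReactionNetwork, params: dict[str, float],
                 state: np.ndarray,
                 ampk_star: Optional[float] = None,
                 rapamycin_star: Optional[float] = None) -> np.ndarray:
    """Instantaneous step input: reset total AMPK* and/or rapamycin*.

    The difference between the requested total and the current total of the
    molecule type is added to (or removed from) the free unmodified monomer
    pool, leaving every complex untouched — the step-stimulus semantics of
    the time-course scenarios.
    """
    y = np.asarray(state, float).copy()
    seed_idx = {}
    for idx, _ in network.seeds:
        sp = network.species[idx]
        if len(sp.molecules) == 1:
            seed_idx[sp.molecules[0].type] = idx
    for mtype, target in (("AMPK", ampk_star), ("rapa", rapamycin_star)):
        if target is None:
            continue
        weights = network.species_total(mtype)
        current = float(weights @ y)
        delta = target - current
        idx = seed_idx[mtype]
        if y[idx] + delta < -1e-9:
            raise ValueError(
                f"cannot remove {-delta:.0f} copies of {mtype}: free pool has "
                f"only {y[idx]:.0f}")
        y[idx] = max(0.0, y[idx] + delta)
    return y


def unstressed_steady_state(network: ReactionNetwork, params: dict[str, float],
                            **kwargs) -> np.ndarray:
    """Steady state of the baseline condition encoded in ``params``
    (nominally AMPK* = 30,000 copies/cell, no rapamycin*)."""
    y, converged = find_steady_state(network, params, **kwargs)
    if not converged:
        raise SimulationError("unstressed condition did not reach steady state")
    return y
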