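"""Exact stochastic simulation of the oscillator circuits.

Each gene of a deterministic (accepted, 24 h-rescaled) model is expanded
into a three-stage description -- promoter state G in {0,1}, mRNA count M,
protein count P -- with transcriptional bursting of fixed statistics:
mean burst frequency Bm = 2 (mRNAs per promoter activation) and mean burst
size Bp = 10 (proteins per mRNA).  The kinetic constants follow from the
ODE parameters alone:

    gamma_p = gamma          (ODE basal degradation of the gene)
    gamma_m = 10 gamma_p     gamma_g = 100 gamma_p
    k_g = beta / (Bm Bp)     k_m = Bm (k_g + gamma_g)     k_p = Bp gamma_m

so that the maximal mean protein level equals the ODE maximum
beta/gamma = 1000.  Hill thresholds act directly on protein counts (both
live on the same 0-1000 scale).  Trajectories are generated with the exact
direct-method Gillespie algorithm and recorded on a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from numba import njit

from .models import (CompiledModel, LeakageConfig, ModelSpec, NO_LEAKAGE,
                     NO_PERTURBATION, PerturbationConfig, build_model,
                     compile_model, _ipow)
from .param_search import ParameterSet, Trajectory

BURST_FREQUENCY = 2.0   # Bm: mean mRNA bursts per promoter activation
BURST_SIZE = 10.0       # Bp: mean proteins per mRNA


@dataclass
class SSAParams:
    """Per-gene kinetic constants of the gene/mRNA/protein expansion,
    plus the bound regulation structure (hills, leakage, perturbation)."""

    model_id: str
    species: tuple[str, ...]
    kg: np.ndarray
    gamma_g: np.ndarray
    km: np.ndarray
    gamma_m: np.ndarray
    kp: np.ndarray
    gamma_p: np.ndarray
    compiled: CompiledModel
    values: dict[str, float]

    @property
    def n_genes(self) -> int:
        return len(self.species)


def convert_to_ssa_params(params: ParameterSet,
                          model: Optional[ModelSpec] = None,
                          leakage: LeakageConfig = NO_LEAKAGE,
                          perturbation: PerturbationConfig = NO_PERTURBATION,
                          ) -> SSAParams:
    """Apply the deterministic->stochastic parameter conversion.

    Hill thresholds, coefficients and targeted-degradation rates are carried
    over unchanged (inside ``compiled``); only the production/degradation
    rates are expanded into promoter/mRNA/protein kinetics.
    """
    spec = model if model is not None else build_model(params.model_id)
    cm = compile_model(spec, params.values, leakage, perturbation)
    gamma_p = cm.gamma.copy()
    gamma_m = 10.0 * gamma_p
    gamma_g = 100.0 * gamma_p
    kg = cm.beta / (BURST_FREQUENCY * BURST_SIZE)
    km = BURST_FREQUENCY * (kg + gamma_g)
    kp = BURST_SIZE * gamma_m
    return SSAParams(cm.model_id, cm.species, kg, gamma_g, km, gamma_m, kp,
                     gamma_p, cm, dict(params.values))


def ode_parameters_from_ssa(sp: SSAParams) -> tuple[np.ndarray, np.ndarray]:
    """Invert the conversion: (beta, gamma) recovered from the kinetics."""
    return sp.kg * BURST_FREQUENCY * BURST_SIZE, sp.gamma_p.copy()


@dataclass
class StochasticTrajectory:
    """Gene state, mRNA and protein counts on a uniform grid."""

    times: np.ndarray
    gene: np.ndarray      # (n_times, n_genes) promoter state in {0,1}
    mrna: np.ndarray      # (n_times, n_genes) integer counts
    protein: np.ndarray   # (n_times, n_genes) integer counts
    species: tuple[str, ...]

    def protein_trajectory(self) -> Trajectory:
        return Trajectory(self.times, self.protein.astype(float), self.species,
                          kind="stochastic")

    def discard_before(self, t0: float) -> "StochasticTrajectory":
        """Drop the burn-in portion and restart the clock at 0."""
        keep = self.times >= t0
        return StochasticTrajectory(self.times[keep] - self.times[keep][0],
                                    self.gene[keep], self.mrna[keep],
                                    self.protein[keep], self.species)


@njit(cache=True)
def _hill_eff(P, i, nterm, w, preg, pkn, pn, pmode, leak_mask, basal):
    """Leakage-wrapped effective transcriptional Hill of gene i."""
    heff = 0.0
    b_i = basal * leak_mask[i]
    for j in range(nterm[i]):
        r = preg[i, j]
        if r < 0:
            h = 1.0
        else:
            vn = _ipow(P[r], pn[i, j])
            if pmode[i, j] == 0:
                h = vn / (pkn[i, j] + vn)
            else:
                h = pkn[i, j] / (pkn[i, j] + vn)
        heff += w[i, j] * (b_i * (1.0 - h) + h)
    return heff


@njit(cache=True)
def _gillespie_kernel(seed, t_end, dt_record,
                      kg, gg, km, gm, kp, gp,
                      nterm, w, preg, pkn, pn, pmode,
                      deg_rate, deg_reg, deg_kn, deg_n, deg_ox, leak_mask,
                      basal, G0, M0, P0):
    np.random.seed(seed)
    n = kg.shape[0]
    nrec = int(round(t_end / dt_record)) + 1
    outG = np.empty((nrec, n), dtype=np.int64)
    outM = np.empty((nrec, n), dtype=np.int64)
    outP = np.empty((nrec, n), dtype=np.int64)
    G = G0.astype(np.float64)
    M = M0.astype(np.float64)
    P = P0.astype(np.float64)
    props = np.empty(6 * n)
    t = 0.0
    irec = 0
    while irec < nrec:
        a0 = 0.0
        for i in range(n):
            heff = _hill_eff(P, i, nterm, w, preg, pkn, pn, pmode,
                             leak_mask, basal)
            deg = gp[i]
            if deg_rate[i] > 0.0:
                v = P[deg_reg[i]] + deg_ox[i]
                vn = _ipow(v, deg_n[i])
                deg += deg_rate[i] * vn / (deg_kn[i] + vn)
            b = 6 * i
            props[b] = kg[i] * (1.0 - G[i])
            props[b + 1] = gg[i] * G[i]
            props[b + 2] = km[i] * G[i] * heff
            props[b + 3] = gm[i] * M[i]
            props[b + 4] = kp[i] * M[i]
            props[b + 5] = deg * P[i]
            a0 += props[b] + props[b + 1] + props[b + 2] + \
                props[b + 3] + props[b + 4] + props[b + 5]
        if a0 <= 0.0:
            while irec < nrec:   # frozen state to the end of the window
                for i in range(n):
                    outG[irec, i] = np.int64(G[i])
                    outM[irec, i] = np.int64(M[i])
                    outP[irec, i] = np.int64(P[i])
                irec += 1
            break
        t_next = t - np.log(np.random.random()) / a0
        while irec < nrec and irec * dt_record <= t_next:
            for i in range(n):
                outG[irec, i] = np.int64(G[i])
                outM[irec, i] = np.int64(M[i])
                outP[irec, i] = np.int64(P[i])
            irec += 1
        if irec >= nrec:
            break
        t = t_next
        r = np.random.random() * a0
        acc = 0.0
        k = 6 * n - 1
        for j in range(6 * n):
            acc += props[j]
            if r < acc:
                k = j
                break
        i = k // 6
        m = k % 6
        if m == 0:
            G[i] = 1.0
        elif m == 1:
            G[i] = 0.0
        elif m == 2:
            M[i] += 1.0
        elif m == 3:
            M[i] -= 1.0
        elif m == 4:
            P[i] += 1.0
        else:
            P[i] -= 1.0
    times = np.arange(nrec) * dt_record
    return times, outG, outM, outP


def initial_state(sp: SSAParams, proteins: Optional[np.ndarray] = None,
                  rng: Optional[np.random.Generator] = None,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial (G, M, P): protein counts as given (default 10% of p_max),
    promoter state drawn at its stationary activation probability, mRNA at
    its conditional mean given the protein levels."""
    n = sp.n_genes
    cm = sp.compiled
    if proteins is None:
        proteins = np.full(n, 0.1 * cm.p_max)
    P = np.round(np.asarray(proteins, float))
    p_on = sp.kg / (sp.kg + sp.gamma_g)
    if rng is None:
        G = np.round(p_on)
    else:
        G = (rng.random(n) < p_on).astype(float)
    heff = np.array([_hill_eff(P, i, cm.nterm, cm.w, cm.preg, cm.pkn, cm.pn,
                               cm.pmode, cm.leak_mask, cm.basal)
                     for i in range(n)])
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(sp.gamma_m > 0, sp.km * p_on * heff / sp.gamma_m, 0.0)
    return G, np.round(M), P


def gillespie_simulate(model: ModelSpec | str,
                       params: ParameterSet | SSAParams,
                       t_end: float,
                       dt_record: float = 0.1,
                       leakage: LeakageConfig = NO_LEAKAGE,
                       perturbation: PerturbationConfig = NO_PERTURBATION,
                       rng: np.random.Generator | int = 0,
                       proteins0: Optional[np.ndarray] = None,
                       ) -> StochasticTrajectory:
    """Run the exact SSA for one parameter set under one condition.

    ``rng`` may be a seed or a Generator; the event sequence is fully
    reproducible from it.  ``proteins0`` sets the initial protein counts
    (typically a point on the deterministic limit cycle).
    """
    spec = build_model(model) if isinstance(model, str) else model
    if isinstance(params, SSAParams):
        ps = ParameterSet(params.model_id, params.values)
    else:
        ps = params
    sp = convert_to_ssa_params(ps, spec, leakage, perturbation)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    G0, M0, P0 = initial_state(sp, proteins0, rng)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    cm = sp.compiled
    times, outG, outM, outP = _gillespie_kernel(
        seed, float(t_end), float(dt_record),
        sp.kg, sp.gamma_g, sp.km, sp.gamma_m, sp.kp, sp.gamma_p,
        cm.nterm, cm.w, cm.preg, cm.pkn, cm.pn, cm.pmode,
        cm.deg_rate, cm.deg_reg, cm.deg_kn, cm.deg_n, cm.deg_ox,
        cm.leak_mask, cm.basal, G0, M0, P0)
    return StochasticTrajectory(times, outG, outM, outP, cm.species)
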