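"""Oscillator circuit definitions.

Nine repressilator-based variants of a minimal circadian oscillator.  Every
gene product ``P`` follows

    dP/dt = beta * Hill(...) - gamma_total(...) * P

where the Hill factors encode transcriptional activation/repression and,
in the post-translationally controlled variants, a *targeted degradation*
term ``gamma_deg * Hill_act(regulator)`` models E3-ligase/26S-proteasome
removal of the protein.  Concentrations are non-dimensionalised so that the
maximum possible steady state of every species is ``p_max = 1000`` molecules
per cell: production rates are always ``beta = 1000 * gamma_basal_total``.

Variants
--------
M1    transcription-only repressilator (X -| Z -| Y -| X ring)
M2    constant transcription, post-translational (degradation) ring
M3    M1 plus a transcriptional positive auto-feedback on each gene
M4    M2 plus a transcriptional positive auto-feedback on each gene
M5    M1 and M2 combined: each gene both transcriptionally repressed and
      degraded under control of the same upstream regulator
CFFL  repressilator whose degradation controllers Ex,Ey,Ez are *activated*
      by their upstream gene (type-3 coherent feed-forward loop)
IFFL  as CFFL but the controllers are *repressed* upstream (type-2
      incoherent feed-forward loop)
NF    controller activated by its own target (negative feedback)
PF    controller repressed by its own target (positive feedback)

A :class:`ModelSpec` is purely topological: it names *parameter slots*
(e.g. ``kappa_tr_Z_X``) that a sampled parameter mapping fills in.
:func:`compile_model` binds numbers to a topology, applies leakage and
perturbations, and produces flat arrays shared by the ODE and SSA engines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from numba import njit

ACTIVATION = "activation"
REPRESSION = "repression"

P_MAX = 1000.0

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "CFFL", "IFFL", "NF", "PF")

#: ring wiring: production of key is repressed by value (M1-style),
#: targeted degradation of key is activated by value (M2-style).
_RING = {"X": "Y", "Y": "Z", "Z": "X"}


@dataclass(frozen=True)
class HillSpec:
    """A single Hill regulation with bound numeric parameters.

    ``activation`` returns v^n / (kappa^n + v^n); ``repression`` returns
    kappa^n / (kappa^n + v^n).  ``kappa`` is the regulator level giving the
    half-maximal effect; ``n`` sets the steepness (cooperativity).
    """

    regulator: str
    kappa: float
    n: int
    mode: str = REPRESSION

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"Hill coefficient must be a positive integer, got {self.n}")
        if self.mode not in (ACTIVATION, REPRESSION):
            raise ValueError(f"unknown Hill mode {self.mode!r}")


def hill(value, spec: HillSpec):
    """Evaluate a Hill function at regulator level ``value`` (>= 0).

    Accepts scalars or arrays; returns a fraction in [0, 1].
    """
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("Hill function argument must be non-negative")
    kn = spec.kappa ** spec.n
    vn = value ** spec.n
    if spec.mode == ACTIVATION:
        out = vn / (kn + vn)
    else:
        out = kn / (kn + vn)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# topology layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillSlot:
    """A Hill regulation whose kappa/n are named parameter slots."""

    regulator: str
    mode: str
    key: str  # slot suffix; parameters are f"kappa_{key}" and f"n_{key}"

    @property
    def kappa_slot(self) -> str:
        return f"kappa_{self.key}"

    @property
    def n_slot(self) -> str:
        return f"n_{self.key}"

    def bind(self, params: Mapping[str, float]) -> HillSpec:
        return HillSpec(self.regulator, float(params[self.kappa_slot]),
                        int(params[self.n_slot]), self.mode)


@dataclass(frozen=True)
class RegulationTerm:
    """One production or targeted-degradation term of a gene.

    ``kind`` is ``transcriptional-production``, ``auto-activation`` or
    ``targeted-degradation``.  Multiple hills in one term multiply
    (AND gate); multiple production *terms* of a gene add.
    """

    kind: str
    hills: tuple[HillSlot, ...]
    rate_slot: str  # "beta_X" / "beta_pos_X" (derived) or "gamma_deg_X"


@dataclass(frozen=True)
class GeneSpec:
    name: str
    production: tuple[RegulationTerm, ...]
    gamma_slot: str                      # basal degradation rate slot
    targeted: Optional[RegulationTerm]   # degradation control, if any


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one oscillator variant."""

    model_id: str
    genes: tuple[GeneSpec, ...]
    p_max: float = P_MAX

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def sampled_slots(self) -> dict[str, str]:
        """Map of independent parameter slot -> slot class.

        Classes: ``gamma`` (basal degradation), ``gamma_deg`` (targeted
        degradation rate), ``kappa``, ``n``, ``rho`` (positive-feedback
        production share, M3/M4 only).  Production rates beta are derived
        (beta_total = 1000 * gamma_basal) and are not listed.
        """
        slots: dict[str, str] = {}
        for g in self.genes:
            slots[g.gamma_slot] = "gamma"
            if g.targeted is not None:
                slots[g.targeted.rate_slot] = "gamma_deg"
            terms = list(g.production) + ([g.targeted] if g.targeted else [])
            for term in terms:
                for h in term.hills:
                    slots[h.kappa_slot] = "kappa"
                    slots[h.n_slot] = "n"
            if len(g.production) > 1:
                slots[f"rho_pos_{g.name}"] = "rho"
        return slots

    def to_json(self) -> str:
        """Machine-readable description (species, terms, parameter slots)."""
        def term(t: RegulationTerm) -> dict:
            return {
                "kind": t.kind,
                "rate_slot": t.rate_slot,
                "hills": [
                    {"regulator": h.regulator, "mode": h.mode,
                     "kappa_slot": h.kappa_slot, "n_slot": h.n_slot}
                    for h in t.hills
                ],
            }
        doc = {
            "model_id": self.model_id,
            "p_max": self.p_max,
            "species": list(self.species),
            "genes": [
                {
                    "name": g.name,
                    "production": [term(t) for t in g.production],
                    "gamma_slot": g.gamma_slot,
                    "targeted_degradation": term(g.targeted) if g.targeted else None,
                }
                for g in self.genes
            ],
            "sampled_slots": self.sampled_slots(),
        }
        return json.dumps(doc, indent=2)


def _core_gene(name: str, *, transcriptional: bool, degradation: bool,
               auto_positive: bool = False, deg_regulator: str | None = None,
               model_tag: str = "") -> GeneSpec:
    """Build one ring gene (X, Y or Z) of a three-gene variant."""
    upstream = _RING[name]
    production = []
    if transcriptional:
        production.append(RegulationTerm(
            "transcriptional-production",
            (HillSlot(upstream, REPRESSION, f"tr_{name}_{upstream}"),),
            f"beta_{name}"))
    else:
        production.append(RegulationTerm(
            "transcriptional-production", (), f"beta_{name}"))
    if auto_positive:
        production.append(RegulationTerm(
            "auto-activation",
            (HillSlot(name, ACTIVATION, f"pos_{name}_{name}"),),
            f"beta_pos_{name}"))
    targeted = None
    if degradation:
        reg = deg_regulator if deg_regulator is not None else upstream
        targeted = RegulationTerm(
            "targeted-degradation",
            (HillSlot(reg, ACTIVATION, f"deg_{name}_{reg}"),),
            f"gamma_deg_{name}")
    return GeneSpec(name, tuple(production), f"gamma_{name}", targeted)


def _e_gene(name: str, target: str, mode: str) -> GeneSpec:
    """Degradation-controller gene E<x> regulated by its ring gene."""
    production = (RegulationTerm(
        "transcriptional-production",
        (HillSlot(target, mode, f"tr_{name}_{target}"),),
        f"beta_{name}"),)
    return GeneSpec(name, production, f"gamma_{name}", None)


def build_model(model_id: str) -> ModelSpec:
    """Return the :class:`ModelSpec` for one of the nine variants."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    ring = ("X", "Y", "Z")
    if model_id == "M1":
        genes = [_core_gene(g, transcriptional=True, degradation=False) for g in ring]
    elif model_id == "M2":
        genes = [_core_gene(g, transcriptional=False, degradation=True) for g in ring]
    elif model_id == "M3":
        genes = [_core_gene(g, transcriptional=True, degradation=False,
                            auto_positive=True) for g in ring]
    elif model_id == "M4":
        genes = [_core_gene(g, transcriptional=False, degradation=True,
                            auto_positive=True) for g in ring]
    elif model_id == "M5":
        genes = [_core_gene(g, transcriptional=True, degradation=True) for g in ring]
    else:
        # six-species motif variants: ring gene <g> is degraded under the
        # control of a dedicated E gene; what regulates that E gene (and how)
        # distinguishes the four motifs.
        deg_controller = {"CFFL": {"X": "Ey", "Y": "Ez", "Z": "Ex"},
                          "IFFL": {"X": "Ey", "Y": "Ez", "Z": "Ex"},
                          "NF":   {"X": "Ex", "Y": "Ey", "Z": "Ez"},
                          "PF":   {"X": "Ex", "Y": "Ey", "Z": "Ez"}}[model_id]
        e_mode = ACTIVATION if model_id in ("CFFL", "NF") else REPRESSION
        genes = [_core_gene(g, transcriptional=True, degradation=True,
                            deg_regulator=deg_controller[g]) for g in ring]
        genes += [_e_gene(f"E{g.lower()}", g, e_mode) for g in ring]
    return ModelSpec(model_id, tuple(genes))


# ---------------------------------------------------------------------------
# leakage and perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeakageConfig:
    """Promoter basal activity: every transcriptional Hill product H is
    replaced by ``basal*(1-H) + H``, keeping the maximum at 1."""

    basal: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.basal <= 1.0:
            raise ValueError(f"basal leakage must be in [0, 1], got {self.basal}")


NO_LEAKAGE = LeakageConfig(0.0)


@dataclass(frozen=True)
class PerturbationConfig:
    """Genetic perturbation of the degradation control.

    kind:
      * ``none``
      * ``null-mutant`` -- targeted gamma_deg of ``target`` set to 0 exactly
      * ``degradation-overexpression`` -- the degradation Hill of ``target``
        sees its regulator shifted by ``magnitude * p_max`` extra molecules
        (constitutive overexpression of the controller, M5-style)
      * ``e-gene-scaling`` -- production rate of E-gene ``target`` multiplied
        by ``magnitude`` (gammas untouched; CFFL/IFFL/NF/PF-style)
    """

    kind: str = "none"
    target: str = "Z"
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        kinds = ("none", "null-mutant", "degradation-overexpression", "e-gene-scaling")
        if self.kind not in kinds:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "degradation-overexpression" and not 0.0 <= self.magnitude <= 0.30:
            raise ValueError("overexpression magnitude must lie in [0, 0.30]")
        if self.kind == "e-gene-scaling" and self.magnitude < 0:
            raise ValueError("e-gene scaling factor must be non-negative")


NO_PERTURBATION = PerturbationConfig()


@dataclass
class CompiledModel:
    """Numeric, flat-array form of a bound model, shared by ODE and SSA.

    Per-gene production is ``beta[g] * H_eff`` with
    ``H_eff = sum_j w[g,j] * leak(prod of hills of term j)`` and total
    degradation ``gamma[g] + deg_rate[g] * Hill_act(P[deg_reg[g]] + deg_ox[g])``.
    """

    model_id: str
    species: tuple[str, ...]
    gamma: np.ndarray          # (n,) basal degradation, 1/hr
    beta: np.ndarray           # (n,) total production (after perturbation), 1/hr
    nterm: np.ndarray          # (n,) number of production terms (1 or 2)
    w: np.ndarray              # (n,2) term weights, sum to 1 per gene
    preg: np.ndarray           # (n,2) regulator index, -1 = unregulated term
    pkn: np.ndarray            # (n,2) kappa**n of production hill
    pn: np.ndarray             # (n,2) Hill coefficient (int)
    pmode: np.ndarray          # (n,2) 0 = activation, 1 = repression
    deg_rate: np.ndarray       # (n,) gamma_deg (0 = no targeted degradation)
    deg_reg: np.ndarray        # (n,) regulator index of degradation hill
    deg_kn: np.ndarray         # (n,) kappa**n of degradation hill
    deg_n: np.ndarray          # (n,) Hill coefficient of degradation hill
    deg_ox: np.ndarray         # (n,) additive overexpression constant (molecules)
    leak_mask: np.ndarray = None  # (n,) 1 where leakage applies (core ring genes)
    basal: float = 0.0
    p_max: float = P_MAX

    @property
    def n_species(self) -> int:
        return len(self.species)


def compile_model(spec: ModelSpec, params: Mapping[str, float],
                  leakage: LeakageConfig = NO_LEAKAGE,
                  perturbation: PerturbationConfig = NO_PERTURBATION) -> CompiledModel:
    """Bind parameter values to a topology; apply leakage and perturbation."""
    n = len(spec.genes)
    idx = {name: i for i, name in enumerate(spec.species)}
    gamma = np.zeros(n)
    beta = np.zeros(n)
    nterm = np.zeros(n, dtype=np.int64)
    w = np.zeros((n, 2))
    preg = np.full((n, 2), -1, dtype=np.int64)
    pkn = np.ones((n, 2))
    pn = np.ones((n, 2), dtype=np.int64)
    pmode = np.zeros((n, 2), dtype=np.int64)
    deg_rate = np.zeros(n)
    deg_reg = np.zeros(n, dtype=np.int64)
    deg_kn = np.ones(n)
    deg_n = np.ones(n, dtype=np.int64)
    deg_ox = np.zeros(n)
    # transcriptional leakage models residual promoter activity of the core
    # clock genes; the E controller genes carry no basal floor
    leak_mask = np.array([0 if g.name.startswith("E") else 1
                          for g in spec.genes], dtype=np.int64)

    for i, g in enumerate(spec.genes):
        gamma[i] = float(params[g.gamma_slot])
        beta[i] = spec.p_max * gamma[i]  # beta = 1000 x basal degradation
        nterm[i] = len(g.production)
        if len(g.production) == 1:
            w[i, 0] = 1.0
        else:
            rho = float(params[f"rho_pos_{g.name}"])
            w[i, 0], w[i, 1] = 1.0 - rho, rho
        for j, term in enumerate(g.production):
            if len(term.hills) > 1:
                raise NotImplementedError("multi-hill production terms not used "
                                          "by the nine variants")
            if term.hills:
                h = term.hills[0].bind(params)
                preg[i, j] = idx[h.regulator]
                pkn[i, j] = h.kappa ** h.n
                pn[i, j] = h.n
                pmode[i, j] = 0 if h.mode == ACTIVATION else 1
        if g.targeted is not None:
            h = g.targeted.hills[0].bind(params)
            deg_rate[i] = float(params[g.targeted.rate_slot])
            deg_reg[i] = idx[h.regulator]
            deg_kn[i] = h.kappa ** h.n
            deg_n[i] = h.n

    if perturbation.kind == "null-mutant":
        i = idx[perturbation.target]
        deg_rate[i] = 0.0
    elif perturbation.kind == "degradation-overexpression":
        i = idx[perturbation.target]
        deg_ox[i] = perturbation.magnitude * spec.p_max
    elif perturbation.kind == "e-gene-scaling":
        i = idx[perturbation.target]
        beta[i] = beta[i] * perturbation.magnitude

    return CompiledModel(spec.model_id, spec.species, gamma, beta, nterm, w,
                         preg, pkn, pn, pmode, deg_rate, deg_reg, deg_kn,
                         deg_n, deg_ox, leak_mask, float(leakage.basal),
                         spec.p_max)


# ---------------------------------------------------------------------------
# ODE right-hand side (numba kernel + public wrapper)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _ipow(v, k):
    r = 1.0
    for _ in range(k):
        r *= v
    return r


@njit(cache=True)
def _rhs_kernel(y, gamma, beta, nterm, w, preg, pkn, pn, pmode,
                deg_rate, deg_reg, deg_kn, deg_n, deg_ox, leak_mask, basal,
                out):
    n = y.shape[0]
    for i in range(n):
        heff = 0.0
        b_i = basal * leak_mask[i]
        for j in range(nterm[i]):
            r = preg[i, j]
            if r < 0:
                h = 1.0
            else:
                v = y[r]
                if v < 0.0:
                    v = 0.0
                vn = _ipow(v, pn[i, j])
                if pmode[i, j] == 0:
                    h = vn / (pkn[i, j] + vn)
                else:
                    h = pkn[i, j] / (pkn[i, j] + vn)
            heff += w[i, j] * (b_i * (1.0 - h) + h)
        gtot = gamma[i]
        if deg_rate[i] > 0.0:
            v = y[deg_reg[i]] + deg_ox[i]
            if v < 0.0:
                v = 0.0
            vn = _ipow(v, deg_n[i])
            gtot += deg_rate[i] * vn / (deg_kn[i] + vn)
        out[i] = beta[i] * heff - gtot * y[i]
    return out


def rhs_function(cm: CompiledModel):
    """Return ``f(t, y) -> dy/dt`` suitable for scipy integrators."""
    gamma, beta, nterm = cm.gamma, cm.beta, cm.nterm
    w, preg, pkn, pn, pmode = cm.w, cm.preg, cm.pkn, cm.pn, cm.pmode
    deg_rate, deg_reg, deg_kn = cm.deg_rate, cm.deg_reg, cm.deg_kn
    deg_n, deg_ox, leak_mask, basal = cm.deg_n, cm.deg_ox, cm.leak_mask, cm.basal

    def f(t, y):
        out = np.empty_like(y)
        return _rhs_kernel(y, gamma, beta, nterm, w, preg, pkn, pn, pmode,
                           deg_rate, deg_reg, deg_kn, deg_n, deg_ox,
                           leak_mask, basal, out)

    return f


def ode_rhs(model: ModelSpec, params: Mapping[str, float], state,
            leakage: LeakageConfig = NO_LEAKAGE,
            perturbation: PerturbationConfig = NO_PERTURBATION) -> np.ndarray:
    """Instantaneous derivative (1/hr) of every species at ``state``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (len(model.genes),):
        raise ValueError(f"state must have length {len(model.genes)}")
    if np.any(state < 0):
        raise ValueError("state must be non-negative")
    cm = compile_model(model, params, leakage, perturbation)
    out = np.empty_like(state)
    return _rhs_kernel(state, cm.gamma, cm.beta, cm.nterm, cm.w, cm.preg,
                       cm.pkn, cm.pn, cm.pmode, cm.deg_rate, cm.deg_reg,
                       cm.deg_kn, cm.deg_n, cm.deg_ox, cm.leak_mask,
                       cm.basal, out)
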