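"""Leakage filtering by isolated three-node motifs.

Each motif has an input gene I (driven as a square pulse: ON for t in
[0, 40), OFF for [40, 80]), an output gene O (repressed by I, as in the
repressilator ring) and a degradation controller E.  What regulates E
distinguishes the motifs:

    CFFL  E activated by I     (type-3 coherent feed-forward loop)
    IFFL  E repressed by I     (type-2 incoherent feed-forward loop)
    NF    E activated by O     (negative feedback)
    PF    E repressed by O     (positive feedback)

Under *transcriptional* control E represses O's production; under
*combined* control the E edge is a targeted-degradation term instead.
All production and degradation rates are 1, all Hill coefficients 8, so
every gene's maximal level is 1.  Transcriptional leakage (basal = 0.2)
is applied to I and O only.  The filtering statistic is

    normalized dO = (O_basalON - O_basalOFF) / 0.2

read at t = 40 (I:ON) and t = 80 (I:OFF); subtracting the combined-control
value from the transcriptional one (``delta normalized dO``) is positive
where the degradation control pushes the leaked output back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

MOTIFS = ("CFFL", "IFFL", "NF", "PF")
CONTROLS = ("transcriptional", "combined")

T_ON = 40.0          # I switches off at t = 40
T_END = 80.0
BASAL_LEVEL = 0.2
_DT = 0.02           # fixed RK4 step; unit rates, smooth dynamics


@dataclass(frozen=True)
class PartialMotifSpec:
    """One partial-motif configuration.

    ``k_input`` is the I->O repression threshold, ``k_ctrl`` the E->O
    regulation threshold (transcriptional repression or degradation
    activation depending on ``control``); the threshold of E's own input
    edge is fixed at ``k_e = 0.5``.
    """

    motif: str
    control: str
    k_input: float = 0.5
    k_ctrl: float = 0.5
    k_e: float = 0.5
    n: int = 8
    basal: float = BASAL_LEVEL

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.control not in CONTROLS:
            raise ValueError(f"unknown control {self.control!r}")


def _act(v, kn, n):
    vn = v ** n
    return vn / (kn + vn)


def _rep(v, kn, n):
    vn = v ** n
    return kn / (kn + vn)


def _integrate(spec: PartialMotifSpec, basal_on: bool,
               k_input: np.ndarray, k_ctrl: np.ndarray,
               ) -> tuple[np.ndarray, np.ndarray]:
    """RK4 integration of the 3-species motif ODE, vectorized over
    threshold grids.  Returns (O at t=40, O at t=80)."""
    n = spec.n
    kin_n = np.asarray(k_input, float) ** n
    kc_n = np.asarray(k_ctrl, float) ** n
    ke_n = spec.k_e ** n
    basal = spec.basal if basal_on else 0.0
    combined = spec.control == "combined"
    motif = spec.motif
    shape = np.broadcast(kin_n, kc_n).shape
    y = np.zeros((3,) + shape)   # I, E, O all start at 0

    def rhs(y, s):
        i_, e_, o_ = y
        drive = s + basal * (1.0 - s)
        di = drive - i_
        u = i_ if motif in ("CFFL", "IFFL") else o_
        if motif in ("CFFL", "NF"):
            he = _act(u, ke_n, n)
        else:
            he = _rep(u, ke_n, n)
        de = he - e_
        prod = _rep(i_, kin_n, n)
        deg = 1.0
        if combined:
            deg = 1.0 + _act(e_, kc_n, n)
        else:
            prod = prod * _rep(e_, kc_n, n)
        prod = basal * (1.0 - prod) + prod
        do = prod - deg * o_
        return np.stack(np.broadcast_arrays(di, de, do))

    reads = []
    for s, t0, t1 in ((1.0, 0.0, T_ON), (0.0, T_ON, T_END)):
        steps = int(round((t1 - t0) / _DT))
        for _ in range(steps):
            k1 = rhs(y, s)
            k2 = rhs(y + 0.5 * _DT * k1, s)
            k3 = rhs(y + 0.5 * _DT * k2, s)
            k4 = rhs(y + _DT * k3, s)
            y = y + (_DT / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        reads.append(y[2].copy())
    return reads[0], reads[1]


def simulate_step_response(spec: PartialMotifSpec, basal_on: bool) -> dict:
    """Output-gene level at the I:ON (t=40) and I:OFF (t=80) read points."""
    o_on, o_off = _integrate(spec, basal_on,
                             np.asarray(spec.k_input), np.asarray(spec.k_ctrl))
    return {"on": float(o_on), "off": float(o_off)}


def normalized_delta_o(spec: PartialMotifSpec) -> dict:
    """(O with leakage - O without leakage) / leakage level, per read point."""
    with_b = simulate_step_response(spec, True)
    without = simulate_step_response(spec, False)
    return {rp: (with_b[rp] - without[rp]) / spec.basal for rp in ("on", "off")}


@dataclass
class ThresholdScan:
    """Grids over (k_input, k_ctrl) in (0.01, 1].

    ``norm_delta`` maps control -> read point -> matrix of normalized dO;
    ``delta`` maps read point -> transcriptional-minus-combined matrix;
    ``output`` maps (control, basal flag as 'on'/'off-state' keys) to the
    raw O read values, used e.g. to locate amplitude collapse in PF.
    Matrix rows index k_input, columns k_ctrl.
    """

    motif: str
    k_input: np.ndarray
    k_ctrl: np.ndarray
    norm_delta: dict
    delta: dict
    output: dict

    def delta_frame(self, read_point: str) -> pd.DataFrame:
        return pd.DataFrame(self.delta[read_point], index=self.k_input,
                            columns=self.k_ctrl)


def scan_thresholds(motif: str, grid_resolution: int = 101,
                    control: Optional[str] = None) -> ThresholdScan:
    """Scan the two free thresholds on a grid and tabulate the filtering
    statistic.  With ``control`` given, only that control's normalized dO
    grids are computed (``delta`` is then empty)."""
    ks = np.linspace(0.01, 1.0, grid_resolution)
    kin = ks[:, None]
    kc = ks[None, :]
    controls = CONTROLS if control is None else (control,)
    norm_delta: dict = {}
    output: dict = {}
    for ctl in controls:
        spec = PartialMotifSpec(motif, ctl)
        on_b, off_b = _integrate(spec, True, kin, kc)
        on_0, off_0 = _integrate(spec, False, kin, kc)
        norm_delta[ctl] = {"on": (on_b - on_0) / spec.basal,
                           "off": (off_b - off_0) / spec.basal}
        output[ctl] = {"on_basal": on_b, "off_basal": off_b,
                       "on_nobasal": on_0, "off_nobasal": off_0}
    delta = {}
    if control is None:
        delta = {rp: norm_delta["transcriptional"][rp] - norm_delta["combined"][rp]
                 for rp in ("on", "off")}
    return ThresholdScan(motif, ks.copy(), ks.copy(), norm_delta, delta, output)
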