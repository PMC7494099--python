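"""End-to-end study orchestration.

For one model: random parameter search -> deterministic screen -> 24 h
rescaling -> stochastic simulation of every accepted set under every
condition (wild type, leakage levels, degradation-control perturbations)
-> ACF scoring -> cohort summaries.  Every task's random stream derives
from the master seed and the (set index, condition label) pair with a
counter-based scheme, so results are reproducible and adding conditions
never perturbs existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (DEFAULT_DECAY_THRESHOLD, DEFAULT_DT_RECORD,
                     DEFAULT_SSA_BURNIN, DEFAULT_SSA_DURATION)
from .models import (LeakageConfig, NO_PERTURBATION, PerturbationConfig,
                     build_model, compile_model, hill, HillSpec, REPRESSION)
from .param_search import (ParameterSet, SearchResult, integrate_ode,
                           parameter_sets_to_frame, search_oscillating_sets)
from .robustness import (DistributionSummary, kl_divergence, score_series,
                         shared_edges, summarize_cohort)
from .ssa import gillespie_simulate


@dataclass(frozen=True)
class Condition:
    """One simulation condition: leakage level plus optional perturbation."""

    label: str
    leakage: float = 0.0
    perturbation: PerturbationConfig = NO_PERTURBATION


WILD_TYPE = Condition("wild-type", 0.0)


@dataclass
class ExperimentConfig:
    model_id: str
    n_parameter_sets: int
    conditions: Sequence[Condition] = (WILD_TYPE,)
    master_seed: int = 0
    ssa_duration: float = DEFAULT_SSA_DURATION
    ssa_burnin: float = DEFAULT_SSA_BURNIN
    dt_record: float = DEFAULT_DT_RECORD
    decay_threshold: float = DEFAULT_DECAY_THRESHOLD
    search_t_end: float = 2000.0
    score_species: str = "X"
    output_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.n_parameter_sets < 1:
            raise ValueError("n_parameter_sets must be >= 1")
        for c in self.conditions:
            if not 0.0 <= c.leakage <= 1.0:
                raise ValueError(f"leakage must be in [0,1], got {c.leakage}")


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    sets: list[ParameterSet]
    records: pd.DataFrame
    summaries: dict
    search: Optional[SearchResult] = None


def _task_rng(master_seed: int, set_index: int, label: str) -> np.random.Generator:
    """Order-independent per-(set, condition) random stream."""
    key = zlib.crc32(label.encode("utf8"))
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(set_index), int(key)))
    return np.random.default_rng(ss)


def limit_cycle_state(ps: ParameterSet, t_settle: float = 240.0) -> np.ndarray:
    """A point on the deterministic limit cycle of a rescaled set (used as
    the stochastic initial condition)."""
    spec = build_model(ps.model_id)
    traj = integrate_ode(spec, ps, t_settle, dt_record=1.0)
    return traj.values[-1]


def simulate_and_score(ps: ParameterSet, condition: Condition,
                       rng: np.random.Generator,
                       proteins0: Optional[np.ndarray] = None,
                       duration: float = DEFAULT_SSA_DURATION,
                       burnin: float = DEFAULT_SSA_BURNIN,
                       dt_record: float = DEFAULT_DT_RECORD,
                       decay_threshold: float = DEFAULT_DECAY_THRESHOLD,
                       species: str = "X") -> dict:
    """One SSA run plus ACF scoring; returns a flat metric record."""
    spec = build_model(ps.model_id)
    traj = gillespie_simulate(spec, ps, burnin + duration, dt_record,
                              LeakageConfig(condition.leakage),
                              condition.perturbation, rng, proteins0)
    kept = traj.discard_before(burnin)
    series = kept.protein[:, spec.species.index(species)].astype(float)
    try:
        res = score_series(series, dt_record, period_hint=24.0,
                           decay_threshold=decay_threshold)
        record = {"decay_rate": res.decay_rate, "sustained":
                  res.classification == "sustained",
                  "fit_success": res.fit_success, "period": res.period,
                  "cos_decay_rate": res.cos_decay_rate,
                  "cos_period": res.cos_period,
                  "n_peaks": int(len(res.peak_values)), "error": ""}
    except ValueError as exc:      # e.g. degenerate constant series
        record = {"decay_rate": np.nan, "sustained": False,
                  "fit_success": False, "period": np.nan, "n_peaks": 0,
                  "error": str(exc)}
    record.update(condition=condition.label, leakage=condition.leakage,
                  perturbation=condition.perturbation.kind,
                  perturbation_magnitude=condition.perturbation.magnitude,
                  model_id=ps.model_id)
    return record


def run_experiment(config: ExperimentConfig,
                   sets: Optional[list[ParameterSet]] = None,
                   ) -> ExperimentResult:
    """Execute search -> convert -> simulate -> score for every
    set x condition; reproducible from config + master seed.

    Pre-searched ``sets`` may be supplied to reuse a cohort across
    experiments.  With ``output_dir`` set, records are written
    incrementally and a rerun resumes from the partial records file.
    """
    search = None
    if sets is None:
        search_rng = _task_rng(config.master_seed, 0, "search:" + config.model_id)
        search = search_oscillating_sets(config.model_id,
                                         config.n_parameter_sets, search_rng,
                                         t_end=config.search_t_end)
        sets = search.sets
    out_dir = Path(config.output_dir) if config.output_dir else None
    done: set[tuple[int, str]] = set()
    old_records: list[dict] = []
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        parameter_sets_to_frame(sets).to_csv(out_dir / "parameter_sets.csv",
                                             index=False)
        rec_path = out_dir / "records.csv"
        if rec_path.exists():
            prev = pd.read_csv(rec_path)
            old_records = prev.to_dict("records")
            done = {(int(r["set_id"]), str(r["condition"])) for r in old_records}

    records: list[dict] = list(old_records)
    for i, ps in enumerate(sets):
        proteins0 = limit_cycle_state(ps)
        for cond in config.conditions:
            if (i, cond.label) in done:
                continue
            rng = _task_rng(config.master_seed, i, cond.label)
            rec = simulate_and_score(
                ps, cond, rng, proteins0, config.ssa_duration,
                config.ssa_burnin, config.dt_record, config.decay_threshold,
                config.score_species)
            rec["set_id"] = i
            records.append(rec)
            if out_dir is not None:
                pd.DataFrame(records).to_csv(out_dir / "records.csv", index=False)
    df = pd.DataFrame(records).sort_values(["set_id", "condition"],
                                           kind="stable").reset_index(drop=True)
    summaries = {c.label: summarize_cohort(df[df["condition"] == c.label])
                 for c in config.conditions}
    if out_dir is not None:
        with open(out_dir / "summaries.json", "w") as fh:
            json.dump(summaries, fh, indent=2)
    return ExperimentResult(config, sets, df, summaries, search)


# ---------------------------------------------------------------------------
# paired condition comparison (decay deltas + distribution shifts)
# ---------------------------------------------------------------------------

def _state_samples(ps: ParameterSet, condition: Condition,
                   rng: np.random.Generator, proteins0, duration, burnin,
                   dt_record) -> dict[str, np.ndarray]:
    """Post-burn-in mRNA/protein/Hill samples of gene X (Hill: transcriptional
    repression of Z by X, where the model has one)."""
    spec = build_model(ps.model_id)
    traj = gillespie_simulate(spec, ps, burnin + duration, dt_record,
                              LeakageConfig(condition.leakage),
                              condition.perturbation, rng, proteins0)
    kept = traj.discard_before(burnin)
    ix = spec.species.index("X")
    out = {"mrna": kept.mrna[:, ix].astype(float),
           "protein": kept.protein[:, ix].astype(float)}
    if "kappa_tr_Z_X" in ps.values:
        hs = HillSpec("X", ps.values["kappa_tr_Z_X"],
                      int(ps.values["n_tr_Z_X"]), REPRESSION)
        out["hill"] = hill(kept.protein[:, ix].astype(float), hs)
    return out


def compare_conditions(result: ExperimentResult, condition_a: str,
                       condition_b: str, n_bins: int = 50,
                       max_sets: Optional[int] = None) -> dict:
    """Paired comparison of two conditions over the same parameter sets.

    Returns the change in sustained fraction, per-set decay-rate deltas,
    and per-set KL divergences KL(b || a) of the mRNA, protein and
    transcriptional-Hill distributions (trajectories are re-generated from
    the stored per-task seeds, so the comparison matches the scored runs).
    """
    cfg = result.config
    labels = {c.label: c for c in cfg.conditions}
    for lab in (condition_a, condition_b):
        if lab not in labels:
            raise ValueError(f"condition {lab!r} not present in the experiment")
    df = result.records
    a = df[df["condition"] == condition_a].set_index("set_id")
    b = df[df["condition"] == condition_b].set_index("set_id")
    if not a.index.equals(b.index):
        raise ValueError("conditions cover different parameter sets")
    rows = []
    set_ids = list(a.index) if max_sets is None else list(a.index)[:max_sets]
    for i in set_ids:
        ps = result.sets[i]
        proteins0 = limit_cycle_state(ps)
        sa = _state_samples(ps, labels[condition_a],
                            _task_rng(cfg.master_seed, i, condition_a),
                            proteins0, cfg.ssa_duration, cfg.ssa_burnin,
                            cfg.dt_record)
        sb = _state_samples(ps, labels[condition_b],
                            _task_rng(cfg.master_seed, i, condition_b),
                            proteins0, cfg.ssa_duration, cfg.ssa_burnin,
                            cfg.dt_record)
        row = {"set_id": i,
               "decay_delta": float(b.loc[i, "decay_rate"] - a.loc[i, "decay_rate"])}
        for var in sa:
            edges = shared_edges(sa[var], sb[var], n_bins=n_bins)
            p = DistributionSummary.from_samples(sb[var], edges)
            q = DistributionSummary.from_samples(sa[var], edges)
            row[f"kl_{var}"] = kl_divergence(p, q)
        rows.append(row)
    pair = pd.DataFrame(rows)
    return {
        "condition_a": condition_a, "condition_b": condition_b,
        "fraction_a": float(a["sustained"].mean()),
        "fraction_b": float(b["sustained"].mean()),
        "fraction_change": float(b["sustained"].mean() - a["sustained"].mean()),
        "per_set": pair,
        "median_kl": {c[3:]: float(pair[c].median())
                      for c in pair.columns if c.startswith("kl_")},
    }
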