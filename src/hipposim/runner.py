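"""Experiment orchestration: configs, presets, seeds, canned experiments.

Every experiment is a pure function of a flat JSON-compatible config plus a
single root seed; the root seed is spawned into per-component child seeds
through ``numpy.random.SeedSequence`` so that (config, seed) reproduces all
outputs byte-identically. The "rat-anatomy" preset carries the anatomical
numbers of the rat hippocampus (12,000 recurrent collaterals per CA3 cell at
2% sparseness, 46 mossy fibers from 10^6 granule cells onto 3x10^5 CA3
cells, 3,600 perforant-path synapses); "rat-desk" is the scaled-down variant
actually simulated on a workstation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import ca3, cann, dentate, heteroassoc, patterns

__all__ = [
    "PRESETS",
    "EXPERIMENTS",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "read_config",
    "write_results",
]

PRESETS: dict[str, dict[str, Any]] = {
    # anatomical numbers for the rat hippocampus
    "rat-anatomy": {
        "c_rc": 12000,
        "a": 0.02,
        "n_ca3": 300_000,
        "fan_in": 46,
        "n_dg": 1_000_000,
        "c_pa": 3600,
        "prefactor_k": 0.235,
    },
    # desk-scale surrogate preserving the dilution and sparseness regime
    "rat-desk": {
        "c_rc": 100,
        "a": 0.05,
        "n_ca3": 1000,
        "fan_in": 46,
        "n_dg": 2000,
        "c_pa": 200,
        "prefactor_k": 0.235,
    },
}


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    preset: str | None = None

    def resolved(self) -> dict[str, Any]:
        """Preset values overlaid by explicit params."""
        base = dict(PRESETS[self.preset]) if self.preset else {}
        base.update(self.params)
        return base


@dataclass
class ExperimentResult:
    summary: dict[str, Any]
    tables: dict[str, pd.DataFrame]
    config: ExperimentConfig
    log: list[str] = field(default_factory=list)

    @property
    def provenance(self) -> dict[str, Any]:
        blob = json.dumps(
            {"experiment": self.config.experiment, "params": self.config.params,
             "seed": self.config.seed, "preset": self.config.preset},
            sort_keys=True,
        )
        return {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": self.config.seed,
        }


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# canned experiments; each takes (resolved params, seed) -> (summary, tables)


def _exp_analytic_report(p: dict, seed: int):
    c_rc = int(p.get("c_rc", 12000))
    a = float(p.get("a", 0.02))
    k = float(p.get("prefactor_k", 0.235))
    n_ca3 = int(p.get("n_ca3", 300_000))
    fan_in = int(p.get("fan_in", 46))
    n_dg = int(p.get("n_dg", 1_000_000))
    c_pa = int(p.get("c_pa", 3600))
    est = ca3.capacity_analytic(c_rc, a, k)
    budget = heteroassoc.backprojection_budget(
        heteroassoc.BackprojectionBudget(c_rc, a, a)
    )
    summary = {
        "p_max_analytic": est.p_max,
        "rc_dilution": c_rc / n_ca3,
        "mossy_dilution": fan_in / n_dg,
        "c_hbp": budget,
        "pa_rc_capacity_ratio": c_pa / c_rc,
        "pa_capacity_analytic": heteroassoc.pa_capacity_analytic(c_pa, a).p_max,
    }
    return summary, {}


def _exp_capacity_scan(p: dict, seed: int):
    n = int(p.get("n", 1000))
    c_values = [int(c) for c in p.get("c_values", [50, 100])]
    a_values = [float(a) for a in p.get("a_values", [0.05])]
    rows = []
    for c in c_values:
        for a in a_values:
            est = ca3.capacity_simulated(n, c, a, seed=seed)
            rows.append(
                {"N": n, "C": c, "a": a, "p_max": est.p_max,
                 "k_hat": est.prefactor_k, "criterion": est.criterion}
            )
    df = pd.DataFrame(rows)
    return {"p_max_by_condition": df["p_max"].tolist()}, {"capacity_scan": df}


def _exp_completion_curve(p: dict, seed: int):
    n = int(p.get("n", 500))
    c = int(p.get("c", 100))
    a = float(p.get("a", 0.05))
    n_pats = int(p.get("p", 10))
    fractions = [float(f) for f in p.get("cue_fractions", np.round(np.arange(0.1, 1.01, 0.1), 2))]
    s_graph, s_pats, s_cue = _child_seeds(seed, 3)
    graph = ca3.build_connectivity(n, c, s_graph)
    ens = patterns.generate_binary_ensemble(n, n_pats, a, s_pats)
    w = ca3.store_auto(ens, graph, ca3.LearningRule(a_prior=a))
    cfg = ca3.RetrievalConfig(a_retrieval=a)
    rows = []
    for frac in fractions:
        ovls = []
        for mu in range(n_pats):
            cue = patterns.make_cue(ens[mu], patterns.CueSpec(frac, seed=s_cue + mu))
            res = ca3.recall_auto(w, cue, cfg)
            ovls.append(patterns.overlap(res.state, ens[mu]))
        rows.append({"cue_fraction": frac, "mean_overlap": float(np.mean(ovls))})
    df = pd.DataFrame(rows)
    return (
        {"mean_overlap_at_half_cue": float(df.loc[np.isclose(df.cue_fraction, 0.5), "mean_overlap"].iloc[0])
         if np.any(np.isclose(df.cue_fraction, 0.5)) else None,
         "monotone": bool(np.all(np.diff(df.mean_overlap) >= -1e-9))},
        {"completion_curve": df},
    )


def _exp_dup_synapse(p: dict, seed: int):
    rep = ca3.duplicate_synapse_experiment(
        int(p.get("n", 800)), int(p.get("c", 80)), float(p.get("a", 0.05)),
        float(p.get("duplicate_fraction", 0.3)), seed,
    )
    df = pd.DataFrame([rep.__dict__])
    return {"p_max_single": rep.p_max_single, "p_max_multi": rep.p_max_multi}, {"dup_synapse": df}


def _exp_grid_to_place(p: dict, seed: int):
    n_ec = int(p.get("n_ec", 50))
    n_dg = int(p.get("n_dg", 500))
    a_dg = float(p.get("a_dg", 0.02))
    epochs = int(p.get("epochs", 20))
    n_positions = int(p.get("n_positions", 100))
    s_pop, s_net, s_train = _child_seeds(seed, 3)
    pop = dentate.GridCellPopulation.random(n_ec, s_pop)
    net0 = dentate.CompetitiveNetwork.random(n_ec, n_dg, a_dg, s_net)
    net1 = dentate.competitive_train(net0, pop, n_positions, epochs, s_train)

    def unit_stats(net):
        # fields are counted on the firing map (post-inhibition); tuning
        # selectivity on the drive map, which is blind to win counts
        rmap = dentate.response_map(net, pop, n_positions)
        dmap = dentate.drive_map(net, pop, n_positions)
        active = np.flatnonzero(rmap.max(axis=0) > 0)
        if active.size == 0:
            return 0.0, None, 0
        n_fields = [dentate.place_field_metrics(rmap[:, u]).n_fields for u in active]
        sparsity = [dentate.place_field_metrics(dmap[:, u]).spatial_sparsity for u in active]
        single = float(np.mean([nf == 1 for nf in n_fields]))
        return single, float(np.mean(sparsity)), int(active.size)

    s0, sp0, na0 = unit_stats(net0)
    s1, sp1, na1 = unit_stats(net1)
    df = pd.DataFrame(
        [{"network": "untrained", "single_field_fraction": s0, "mean_spatial_sparsity": sp0, "n_active": na0},
         {"network": "trained", "single_field_fraction": s1, "mean_spatial_sparsity": sp1, "n_active": na1}]
    )
    return (
        {"single_field_fraction_untrained": s0, "single_field_fraction_trained": s1,
         "spatial_sparsity_untrained": sp0, "spatial_sparsity_trained": sp1},
        {"grid_to_place": df},
    )


def _exp_mossy_separation(p: dict, seed: int):
    n_dg = int(p.get("n_dg", 2000))
    n_ca3 = int(p.get("n_ca3", 600))
    fan_in = int(p.get("fan_in", 46))
    a_dg = float(p.get("a_dg", 0.05))
    a_ca3 = float(p.get("a_ca3", 0.05))
    target_r = float(p.get("input_correlation", 0.5))
    n_pats = int(p.get("p", 20))
    n_seeds = int(p.get("n_seeds", 20))
    rows = []
    for s in _child_seeds(seed, n_seeds):
        s_in, s_proj = _child_seeds(s, 2)
        ens = patterns.generate_correlated_ensemble(n_dg, n_pats, a_dg, target_r, s_in)
        proj = dentate.build_mossy_projection(n_dg, n_ca3, s_proj, fan_in)
        outs = np.stack([dentate.mossy_project(r, proj, a_ca3) for r in ens])
        rows.append(
            {"seed": s,
             "input_correlation": patterns.mean_pairwise_correlation(ens.patterns),
             "output_correlation": patterns.mean_pairwise_correlation(outs),
             "separation_index": dentate.separation_index(ens, outs)}
        )
    df = pd.DataFrame(rows)
    frac = float(np.mean(df.separation_index < 1))
    return {"mean_separation_index": float(df.separation_index.mean()),
            "fraction_separating": frac}, {"mossy_separation": df}


def _exp_pa_generalization(p: dict, seed: int):
    n_in = int(p.get("n_in", 500))
    n_out = int(p.get("n_out", 500))
    c_pa = int(p.get("c_pa", 200))
    a = float(p.get("a", 0.05))
    n_pats = int(p.get("p", 5))
    frac = float(p.get("cue_fraction", 0.5))
    s_net, s_in, s_out, s_cue = _child_seeds(seed, 4)
    pa = heteroassoc.build_associator(n_in, n_out, c_pa, a, s_net)
    xs = patterns.generate_binary_ensemble(n_in, n_pats, a, s_in).patterns
    ys = patterns.generate_binary_ensemble(n_out, n_pats, a, s_out).patterns
    pa = heteroassoc.pa_store(pa, list(zip(xs, ys)), ca3.LearningRule(a_prior=a))
    fwd, rev = [], []
    for mu in range(n_pats):
        cue = patterns.make_cue(xs[mu], patterns.CueSpec(frac, seed=s_cue + mu))
        fwd.append(patterns.overlap(heteroassoc.pa_recall(pa, cue), ys[mu]))
        if n_in == n_out:
            rev.append(patterns.overlap(heteroassoc.pa_recall(pa, ys[mu]), xs[mu]))
    summary = {"mean_forward_overlap": float(np.mean(fwd)),
               "mean_reverse_overlap": float(np.mean(rev)) if rev else None,
               "chance_level": a}
    return summary, {"pa_generalization": pd.DataFrame({"forward": fwd, "reverse": rev or [np.nan] * n_pats})}


def _exp_snr_scaling(p: dict, seed: int):
    c_values = [int(c) for c in p.get("c_values", [100, 400, 1600])]
    table = heteroassoc.recall_signal_snr(
        c_values,
        n_in=int(p.get("n_in", 2000)),
        a=float(p.get("a", 0.05)),
        p=int(p.get("p", 20)),
        seeds=_child_seeds(seed, int(p.get("n_seeds", 5))),
    )
    df = pd.DataFrame({"C": table.c_values, "snr": table.snr})
    return {"loglog_slope": table.slope}, {"snr_scaling": df}


def _exp_backprojection_chain(p: dict, seed: int):
    sizes = [int(x) for x in p.get("sizes", [300, 400, 600, 1000])]
    a = float(p.get("a", 0.05))
    n_pats = int(p.get("p", 3))
    c_budget = int(p.get("c_budget", heteroassoc.backprojection_budget(
        heteroassoc.BackprojectionBudget(int(p.get("c_ref", 150)), a, a))))
    n_seeds = int(p.get("n_seeds", 5))
    halvings = int(p.get("halvings", 3))
    rows = []
    for s in _child_seeds(seed, n_seeds):
        for j in range(halvings + 1):
            c = max(1, c_budget // (2**j))
            h = heteroassoc.build_hierarchy(sizes, min(c, sizes[0]), a, n_pats, s)
            finals = []
            for mu in range(n_pats):
                _, ovl = heteroassoc.hierarchy_recall(h, h.stage_patterns[0][mu], mu)
                finals.append(ovl[-1])
            rows.append({"seed": s, "C": c, "budget_fraction": 1 / 2**j,
                         "final_overlap": float(np.mean(finals))})
    df = pd.DataFrame(rows)
    by_c = df.groupby("budget_fraction").final_overlap.mean()
    return (
        {"final_overlap_at_budget": float(by_c.get(1.0)),
         "final_overlap_at_half_budget": float(by_c.get(0.5))},
        {"backprojection_chain": df},
    )


def _exp_mixed_object_place(p: dict, seed: int):
    n_c = int(p.get("n_continuous", 1000))
    n_d = int(p.get("n_discrete", 500))
    sigma = float(p.get("sigma", 20.0))
    centers = [int(c) for c in p.get("centers", [300, 500])]
    n_obj = int(p.get("n_object_units", 25))
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    sets, pool = [], np.arange(n_d)
    for _ in centers:
        pick = rng.choice(pool, size=n_obj, replace=False)
        sets.append(frozenset(int(i) for i in pick))
        pool = np.setdiff1d(pool, pick)
    net = cann.CannNetwork(n_c, n_d, k_continuous=int(round(4 * sigma)), k_discrete=n_obj)
    mems = [cann.MixedMemory(c, sigma, s) for c, s in zip(centers, sets)]
    net = cann.cann_store(net, mems)
    rows = []
    for mem in mems:
        full = cann.mixed_pattern(mem, net)
        res_p = cann.cann_recall(net, full, mode="object-to-place")
        center_hat = cann.bump_center(res_p.continuous(net))
        err = min(abs(center_hat - mem.center), n_c - abs(center_hat - mem.center))
        res_o = cann.cann_recall(net, full, mode="place-to-object")
        got = set(np.flatnonzero(res_o.discrete(net) > 0).tolist())
        jac = len(got & set(mem.discrete_set)) / len(got | set(mem.discrete_set))
        rows.append({"center": mem.center, "center_error": float(err), "jaccard": float(jac)})
    df = pd.DataFrame(rows)
    return (
        {"max_center_error": float(df.center_error.max()),
         "min_jaccard": float(df.jaccard.min())},
        {"mixed_object_place": df},
    )


EXPERIMENTS: dict[str, Callable] = {
    "analytic_report": _exp_analytic_report,
    "capacity_scan": _exp_capacity_scan,
    "completion_curve": _exp_completion_curve,
    "dup_synapse": _exp_dup_synapse,
    "grid_to_place": _exp_grid_to_place,
    "mossy_separation": _exp_mossy_separation,
    "pa_generalization": _exp_pa_generalization,
    "snr_scaling": _exp_snr_scaling,
    "backprojection_chain": _exp_backprojection_chain,
    "mixed_object_place": _exp_mixed_object_place,
}

_COMMON_KEYS = {"experiment", "seed", "preset", "out"}
_KNOWN_KEYS: dict[str, set[str]] = {
    "analytic_report": {"c_rc", "a", "prefactor_k", "n_ca3", "fan_in", "n_dg", "c_pa"},
    "capacity_scan": {"n", "c_values", "a_values"},
    "completion_curve": {"n", "c", "a", "p", "cue_fractions"},
    "dup_synapse": {"n", "c", "a", "duplicate_fraction"},
    "grid_to_place": {"n_ec", "n_dg", "a_dg", "epochs", "n_positions"},
    "mossy_separation": {"n_dg", "n_ca3", "fan_in", "a_dg", "a_ca3",
                         "input_correlation", "p", "n_seeds"},
    "pa_generalization": {"n_in", "n_out", "c_pa", "a", "p", "cue_fraction"},
    "snr_scaling": {"c_values", "n_in", "a", "p", "n_seeds"},
    "backprojection_chain": {"sizes", "a", "p", "c_budget", "c_ref", "n_seeds", "halvings"},
    "mixed_object_place": {"n_continuous", "n_discrete", "sigma", "centers", "n_object_units"},
}


def _validate(config: ExperimentConfig) -> None:
    if config.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; "
            f"known: {sorted(EXPERIMENTS)}"
        )
    if config.preset is not None and config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}; known: {sorted(PRESETS)}")
    allowed = _KNOWN_KEYS[config.experiment] | set(PRESETS["rat-anatomy"])
    unknown = set(config.params) - allowed
    if unknown:
        raise ValueError(f"unknown config keys for {config.experiment}: {sorted(unknown)}")


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Validate, dispatch, and time one canned experiment."""
    _validate(config)
    t0 = time.perf_counter()
    summary, tables = EXPERIMENTS[config.experiment](config.resolved(), config.seed)
    log = [
        f"experiment={config.experiment}",
        f"seed={config.seed}",
        f"preset={config.preset}",
        f"elapsed_s={time.perf_counter() - t0:.3f}",
    ]
    return ExperimentResult(summary, tables, config, log)


def read_config(path: str | Path) -> ExperimentConfig:
    """Read a flat JSON config; unknown keys are rejected at run time."""
    try:
        doc = json.loads(Path(path).read_text())
    except OSError as exc:
        raise OSError(f"cannot read config {path}: {exc}") from exc
    if "experiment" not in doc:
        raise ValueError(f"config {path} lacks an 'experiment' key")
    params = {k: v for k, v in doc.items() if k not in _COMMON_KEYS}
    return ExperimentConfig(
        experiment=doc["experiment"],
        params=params,
        seed=int(doc.get("seed", 0)),
        preset=doc.get("preset"),
    )


def write_results(result: ExperimentResult, out_dir: str | Path) -> Path:
    """Write resolved config, JSON summary, CSV tables, and a run log."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        resolved = {
            "experiment": result.config.experiment,
            "seed": result.config.seed,
            "preset": result.config.preset,
            **result.config.params,
        }
        (out / "config.json").write_text(json.dumps(resolved, indent=1, default=str))
        (out / "summary.json").write_text(
            json.dumps({**result.summary, "provenance": result.provenance},
                       indent=1, default=str)
        )
        for name, df in result.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "run.log").write_text("\n".join(result.log) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write results under {out}: {exc}") from exc
    return out
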