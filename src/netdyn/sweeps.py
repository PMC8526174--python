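"""Parameter-sweep drivers for SC/FC experiments.

Three sweep axes are supported for each dynamics family:

- ``randomization``: grid of randomization fractions of the base graph
  (degree-preserving double-edge swaps, or single-endpoint rewiring for
  ring lattices), with the swap budget per 10% configurable (defaults: 50
  for 60-node modular/ring graphs, 20 for the hierarchical graph);
- ``coupling``: grid of coupling strengths k (Kuramoto and logistic
  maps; the SER automaton has no coupling parameter);
- ``intrinsic``: grid over the model's intrinsic parameter — recovery
  probability p (SER), width of the natural-frequency interval
  (Kuramoto), midpoint of the R interval at fixed width 0.2 (logistic).

For each grid point the driver regenerates the graph for ``n_graph_seeds``
independent seeds, runs the dynamics ensemble, computes the SC/FCsim and
SC/FCseq Pearson correlations, and aggregates: mean ± sd across graph
seeds (SER, Kuramoto, FHN) or across runs pooled over graph seeds
(logistic maps, whose per-run-then-average convention differs).

Seeding is counter-based: a master seed spawns one child per (grid point,
graph seed) via ``numpy.random.SeedSequence`` spawn keys, so results are
independent of execution order and bit-identical between serial and
parallel execution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import graphs
from .fhn import FHNParams, _simulate_batch as _fhn_batch, fhn_fc_pair
from .kuramoto import KuramotoParams, kuramoto_ensemble_fc
from .logistic import LogisticParams, logistic_ensemble_scfc
from .scfc import scfc_correlation
from .ser import SERParams, ser_ensemble_fc

__all__ = ["GraphSpec", "SweepSpec", "make_graph", "run_sweep",
           "summarize_and_plot", "spec_from_config"]


@dataclass
class GraphSpec:
    """Named graph generator plus parameters (see :mod:`netdyn.graphs`)."""

    model: str = "modular"  # modular | erdos_renyi | barabasi_albert |
    #                         watts_strogatz | hierarchical | file
    parameters: dict = field(default_factory=dict)

    def default_swaps_per_level(self) -> int:
        # 10% of randomization ~ 50 swaps on the 420-edge modular and ring
        # graphs, 20 on the 174-edge hierarchical graph
        return 20 if self.model == "hierarchical" else 50


def make_graph(spec: GraphSpec, seed, require_connected: bool = True) -> np.ndarray:
    """Build the structural graph for one seed; resample until connected."""
    p = dict(spec.parameters)
    if spec.model == "modular":
        factory = lambda rng: graphs.make_modular(
            p.get("n_cliques", 4), p.get("clique_size", 15),
            p.get("rewire_p", 0.23), rng)
    elif spec.model in ("erdos_renyi", "barabasi_albert", "watts_strogatz"):
        n = p.pop("n", 60)
        factory = lambda rng: graphs.make_standard(spec.model, n, rng, **p)
    elif spec.model == "hierarchical":
        A = graphs.make_hierarchical(p.get("levels", 3))
        return A  # deterministic
    elif spec.model == "file":
        from .io import read_graph

        return read_graph(p["path"])
    else:
        raise ValueError(f"unknown graph model {spec.model!r}")
    if not require_connected:
        return factory(np.random.default_rng(seed))
    return graphs.ensure_connected(factory, seed)


@dataclass
class SweepSpec:
    """Full description of one sweep experiment."""

    dynamics: str  # ser | kuramoto | logistic | fhn
    graph: GraphSpec = field(default_factory=GraphSpec)
    axis: str = "randomization"  # randomization | coupling | intrinsic
    grid: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    n_graph_seeds: int = 10
    params: Any = None  # dynamics-specific dataclass; defaults if None
    master_seed: int = 0
    swaps_per_level: int | None = None  # swaps per 10% randomization

    def __post_init__(self):
        if self.dynamics not in ("ser", "kuramoto", "logistic", "fhn"):
            raise ValueError(f"unknown dynamics {self.dynamics!r}")
        if self.axis not in ("randomization", "coupling", "intrinsic"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        g = list(self.grid)
        if g != sorted(g) and g != sorted(g, reverse=True):
            raise ValueError("grid must be monotone")
        if self.dynamics == "ser" and self.axis == "coupling":
            raise ValueError("the SER automaton has no coupling parameter")
        if self.params is None:
            self.params = _DEFAULT_PARAMS[self.dynamics]()


_DEFAULT_PARAMS = {
    "ser": SERParams,
    "kuramoto": KuramotoParams,
    "logistic": LogisticParams,
    "fhn": FHNParams,
}


def _child_rng(master_seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    )


def _cell_key(value: float) -> int:
    """Stable 32-bit key for one grid value.

    Child seeds are keyed by (grid value, graph seed) rather than grid
    position, so a cell's result is identical whether it is computed inside
    a full sweep, alone, serially or in parallel.
    """
    import struct
    import zlib

    return zlib.crc32(struct.pack("<d", float(value)))


def _apply_axis(dynamics: str, params, axis: str, value: float):
    """Return a copy of ``params`` with the swept parameter set."""
    if axis == "randomization":
        return params
    if axis == "coupling":
        return dataclasses.replace(params, k=value)
    # intrinsic
    if dynamics == "ser":
        return dataclasses.replace(params, p=value)
    if dynamics == "kuramoto":
        lo, hi = params.omega_interval
        mid = 0.5 * (lo + hi)
        return dataclasses.replace(
            params, omega_interval=(mid - value / 2.0, mid + value / 2.0)
        )
    if dynamics == "logistic":
        return dataclasses.replace(
            params, r_interval=(value - 0.1, value + 0.1)
        )
    raise ValueError(f"no intrinsic axis for {dynamics}")


def _randomized_graph(A0, spec: SweepSpec, fraction: float, rng):
    """Randomize/rewire ``A0`` to the given fraction of the full schedule."""
    per_level = spec.swaps_per_level or spec.graph.default_swaps_per_level()
    n_moves = int(round(fraction * 10 * per_level))
    if n_moves == 0:
        return A0
    if spec.graph.model == "watts_strogatz":
        return graphs.rewire_one_endpoint(A0, n_moves, rng)
    return graphs.randomize_degree_preserving(A0, n_moves, rng)


def _point_scfc(A, dynamics: str, params, rng) -> tuple:
    """Run one dynamics ensemble on one graph; return (r_sim, r_seq) plus
    per-run vectors for the conventions that average per run."""
    if dynamics == "ser":
        fc = ser_ensemble_fc(A, params, rng)
        return (
            scfc_correlation(A, fc.C.astype(float)).r,
            scfc_correlation(A, fc.Sm.astype(float)).r,
            None,
        )
    if dynamics == "kuramoto":
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            fc = kuramoto_ensemble_fc(A, params, rng)
        return (
            scfc_correlation(A, fc.C).r,
            scfc_correlation(A, fc.Sm).r,
            None,
        )
    if dynamics == "logistic":
        s = logistic_ensemble_scfc(A, params, rng)
        return s.mean_r_sim, s.mean_r_seq, (s.r_sim_runs, s.r_seq_runs)
    if dynamics == "fhn":
        x_runs = _fhn_batch(A, params, rng, params.n_runs)
        r_sim = np.empty(params.n_runs)
        r_seq = np.empty(params.n_runs)
        for r in range(params.n_runs):
            pair = fhn_fc_pair(x_runs[r], params)
            r_sim[r] = scfc_correlation(A, pair.C.astype(float)).r
            r_seq[r] = scfc_correlation(A, pair.Sm.astype(float)).r
        return float(np.nanmean(r_sim)), float(np.nanmean(r_seq)), (r_sim, r_seq)
    raise ValueError(dynamics)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Execute the sweep; returns one row per grid point.

    Columns: ``axis_value, mean_r_sim, sd_r_sim, mean_r_seq, sd_r_seq, n,
    diagnostics``.  Aggregation is mean ± sd across graph seeds (SER,
    Kuramoto, FHN) or across runs pooled over graph seeds (logistic).
    Deterministic given ``master_seed``; infeasible grid points are
    recorded as NaN rows with a diagnostic and the sweep continues.
    """
    rows = []
    per_run_convention = spec.dynamics == "logistic"
    for value in spec.grid:
        params = _apply_axis(spec.dynamics, spec.params, spec.axis, value)
        sims, seqs = [], []
        pooled_sim, pooled_seq = [], []
        diag = ""
        for gs in range(spec.n_graph_seeds):
            rng = _child_rng(spec.master_seed, _cell_key(value), gs)
            graph_seed = int(rng.integers(2**31))
            try:
                A = make_graph(spec.graph, graph_seed)
                if spec.axis == "randomization":
                    A = _randomized_graph(A, spec, value, rng)
                r_sim, r_seq, per_run = _point_scfc(A, spec.dynamics, params, rng)
            except (graphs.RandomizationError, graphs.GraphParameterError,
                    FloatingPointError) as err:
                diag = f"graph seed {gs}: {err}"
                continue
            sims.append(r_sim)
            seqs.append(r_seq)
            if per_run is not None:
                pooled_sim.extend(per_run[0].tolist())
                pooled_seq.extend(per_run[1].tolist())
        if not sims:
            rows.append({"axis_value": value, "mean_r_sim": np.nan,
                         "sd_r_sim": np.nan, "mean_r_seq": np.nan,
                         "sd_r_seq": np.nan, "n": 0,
                         "diagnostics": diag or "no successful graph seeds"})
            continue
        if per_run_convention:
            sim_arr, seq_arr = np.asarray(pooled_sim), np.asarray(pooled_seq)
            n_agg = sim_arr.size
        else:
            sim_arr, seq_arr = np.asarray(sims), np.asarray(seqs)
            n_agg = sim_arr.size
        rows.append(
            {
                "axis_value": value,
                "mean_r_sim": float(np.nanmean(sim_arr)),
                "sd_r_sim": float(np.nanstd(sim_arr)),
                "mean_r_seq": float(np.nanmean(seq_arr)),
                "sd_r_seq": float(np.nanstd(seq_arr)),
                "n": int(n_agg),
                "diagnostics": diag,
            }
        )
    return pd.DataFrame(rows)


def summarize_and_plot(result: pd.DataFrame, out_prefix) -> list[str]:
    """Write a tidy CSV (one row per grid point per FC class) and a
    two-curve error-bar figure.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(result) == 0:
        raise ValueError("empty sweep result")
    tidy_rows = []
    for _, row in result.iterrows():
        for cls in ("sim", "seq"):
            tidy_rows.append(
                {
                    "axis_value": row["axis_value"],
                    "fc_class": cls,
                    "mean_r": row[f"mean_r_{cls}"],
                    "sd_r": row[f"sd_r_{cls}"],
                    "n": row["n"],
                    "diagnostics": row["diagnostics"],
                }
            )
    tidy = pd.DataFrame(tidy_rows)
    csv_path = f"{out_prefix}.csv"
    tidy.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cls, color, label in (
        ("sim", "tab:blue", "SC/FCsim (co-activation)"),
        ("seq", "tab:red", "SC/FCseq (sequential)"),
    ):
        ax.errorbar(
            result["axis_value"], result[f"mean_r_{cls}"],
            yerr=result[f"sd_r_{cls}"], marker="o", capsize=3,
            color=color, label=label,
        )
    ax.axhline(0.0, lw=0.5, color="gray")
    ax.set_xlabel("swept parameter")
    ax.set_ylabel("SC/FC correlation")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig_path = f"{out_prefix}.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return [csv_path, fig_path]


def spec_from_config(config: dict) -> SweepSpec:
    """Build a :class:`SweepSpec` from a (YAML-loaded) config mapping.

    Keys: ``dynamics``, ``axis``, ``grid``, ``n_graph_seeds``,
    ``master_seed``, ``swaps_per_level``, ``graph`` (``model`` +
    ``parameters``) and ``params`` (fields of the dynamics' parameter
    dataclass).
    """
    cfg = dict(config)
    graph_cfg = cfg.pop("graph", {}) or {}
    gspec = GraphSpec(
        model=graph_cfg.get("model", "modular"),
        parameters=dict(graph_cfg.get("parameters", {}) or {}),
    )
    dynamics = cfg.pop("dynamics")
    params_cfg = cfg.pop("params", {}) or {}
    params_cls = _DEFAULT_PARAMS[dynamics]
    for key in ("omega_interval", "r_interval"):
        if key in params_cfg:
            params_cfg[key] = tuple(params_cfg[key])
    params = params_cls(**params_cfg)
    grid = tuple(cfg.pop("grid", SweepSpec.__dataclass_fields__["grid"].default))
    return SweepSpec(
        dynamics=dynamics, graph=gspec, params=params, grid=grid, **cfg
    )
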