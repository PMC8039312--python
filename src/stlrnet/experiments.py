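"""End-to-end training protocol: rule × context runs and the 2×2 grid.

One experiment generates the pattern set, builds the context sequence,
trains the configured estimator for one update per frame, and characterizes
the pooled weight distribution before and after training (histogram, mode
report, per-step branch fractions, final outputs).  The grid runs the four
rule×context conditions on a shared pattern set and shared initial weights
and additionally measures the completion/discrimination contrast: replicate
networks with identical initial weights trained on the five similar
same-context sequences, compared by the pairwise Hamming distances of their
final outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    ModeReport,
    SubsetFractions,
    WeightDistribution,
    count_modes,
    mean_offdiagonal,
    output_discrimination_matrix,
    subset_fractions,
    weight_histogram,
    weight_input_similarity,
)
from .network import STLRNetwork, HebbianNetwork
from .patterns import (
    InputSequence,
    PatternSet,
    generate_pattern_set,
    make_different_context_sequence,
    make_same_context_sequence,
    save_pattern_set,
    save_sequence,
)
from .plasticity import normalized_state

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "build_estimator",
    "run_experiment",
    "run_grid_and_report",
    "run_completion_discrimination",
    "GRID_CONDITIONS",
]

GRID_CONDITIONS = (
    ("heblr", "same"),
    ("heblr", "different"),
    ("stlr", "same"),
    ("stlr", "different"),
)


@dataclass
class ExperimentConfig:
    """Full configuration of one training run.

    Seeds are derived deterministically from ``seed``: pattern set uses
    ``seed``, randomized sequences ``seed + 1``, initial weights ``seed + 2``
    — so conditions run at the same ``seed`` share patterns and weights.
    """

    # input construction
    n: int = 120
    k: int = 5
    hd: int = 10
    ones_count: int | None = None  # None -> n/2
    t_len: int = 5
    rule: Literal["heblr", "stlr"] = "heblr"
    context: Literal["same", "different"] = "same"
    sequence_mode: Literal["canonical", "randomized"] = "canonical"
    same_pattern_index: int = 0
    # plasticity
    dw: float = 0.25
    eta: float | str = "auto"
    theta1: float | str = "auto"
    theta2: float | str = "auto"
    upper_quantile: float = 0.60
    lower_quantile: float = 0.40
    coincidence: Literal["approximate", "exact"] = "approximate"
    normalized: bool = True
    weight_low: float = 0.0
    weight_high: float = 1.0
    # analysis
    n_bins: int = 50
    smooth_window: int = 5
    min_prominence_frac: float = 0.10
    histogram_source: Literal["raw", "normalized"] = "raw"
    pool: Literal["active", "all"] = "active"
    # bookkeeping
    seed: int = 0
    store_history: bool = True
    outdir: str | None = None

    def resolved_ones_count(self) -> int:
        return self.n // 2 if self.ones_count is None else self.ones_count

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class ExperimentResult:
    """Artifacts of one training run; sufficient to reproduce it."""

    config: dict  # resolved config (auto thresholds replaced by values)
    pattern_set: PatternSet
    sequence: InputSequence
    estimator: object
    hist_initial: WeightDistribution
    hist_final: WeightDistribution
    modes_initial: ModeReport
    modes_final: ModeReport
    qrp: pd.DataFrame  # per-step mean branch fractions
    qrp_final: SubsetFractions
    outputs_initial: np.ndarray  # (t_len, n_out) firing per frame, initial weights
    outputs_final: np.ndarray  # (t_len, n_out) firing per frame, trained weights
    similarity_assignments: np.ndarray  # neurons best-matching each pattern

    def summary(self) -> dict:
        mr0, mr1 = self.modes_initial, self.modes_final
        return {
            "config": self.config,
            "n_modes_initial": mr0.n_modes,
            "n_modes_final": mr1.n_modes,
            "mode_locations_final": [round(v, 6) for v in mr1.mode_locations],
            "mode_prominences_final": [round(v, 6) for v in mr1.prominences],
            "qrp_final_mean": {
                "q": _nanmean(self.qrp_final.q),
                "r": _nanmean(self.qrp_final.r),
                "p": _nanmean(self.qrp_final.p),
            },
            "n_active_inputs": int(self.estimator.active_mask_.sum()),
            "final_output_ones": int(self.outputs_final[-1].sum())
            if len(self.outputs_final)
            else None,
            "similarity_assignment_counts": self.similarity_assignments.tolist(),
        }


def _nanmean(a) -> float:
    a = np.asarray(a, dtype=float)
    return float(np.nanmean(a)) if np.isfinite(a).any() else float("nan")


def build_estimator(cfg: ExperimentConfig):
    """Instantiate the configured plasticity estimator (unfitted)."""
    common = dict(
        dw=cfg.dw,
        eta=cfg.eta,
        weight_low=cfg.weight_low,
        weight_high=cfg.weight_high,
        store_history=cfg.store_history,
        random_state=cfg.seed + 2,
    )
    if cfg.rule == "heblr":
        return HebbianNetwork(**common)
    if cfg.rule == "stlr":
        return STLRNetwork(
            theta1=cfg.theta1,
            theta2=cfg.theta2,
            upper_quantile=cfg.upper_quantile,
            lower_quantile=cfg.lower_quantile,
            coincidence=cfg.coincidence,
            normalized=cfg.normalized,
            **common,
        )
    raise ValueError(f"rule must be 'heblr' or 'stlr', got {cfg.rule!r}")


def build_sequence(cfg: ExperimentConfig, ps: PatternSet) -> InputSequence:
    if cfg.context == "same":
        seq = make_same_context_sequence(ps[cfg.same_pattern_index], t_len=max(cfg.t_len, 1))
        if cfg.t_len == 0:
            seq = InputSequence(seq.frames[:0], context="same")
        return seq
    if cfg.context == "different":
        return make_different_context_sequence(
            ps, mode=cfg.sequence_mode, t_len=cfg.t_len, seed=cfg.seed + 1
        )
    raise ValueError(f"context must be 'same' or 'different', got {cfg.context!r}")


def _diagnostic_coincidence(est, w, x):
    """Normalized coincidence matrix used for branch-fraction diagnostics."""
    _, w_t, s_t = normalized_state(w, x)
    return np.where(np.asarray(x) > 0, w_t * s_t[:, None], 0.0)


def _diagnostic_thresholds(cfg: ExperimentConfig, est, w0, x0) -> tuple[float, float]:
    """Thresholds for branch-fraction diagnostics.

    STLR estimators carry their own resolved thresholds; for Hebbian runs the
    same quantile procedure is applied to the initial coincidence matrix so
    the q/r/p trajectory is a comparable diagnostic across rules.
    """
    if hasattr(est, "theta1_"):
        return est.theta1_, est.theta2_
    vals = _diagnostic_coincidence(est, w0, x0)[:, np.asarray(x0) > 0].ravel()
    return (
        float(np.quantile(vals, cfg.upper_quantile)),
        float(np.quantile(vals, cfg.lower_quantile)),
    )


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run one rule × context training experiment end to end."""
    ones = cfg.resolved_ones_count()
    try:
        ps = generate_pattern_set(cfg.n, cfg.k, cfg.hd, ones, seed=cfg.seed)
        seq = build_sequence(cfg, ps)
        est = build_estimator(cfg)
        est.fit(seq.frames)
    except (ValueError, TypeError) as exc:
        raise type(exc)(f"[rule={cfg.rule}, context={cfg.context}] {exc}") from exc

    columns = None
    if cfg.pool == "active" and est.active_mask_.any():
        columns = est.active_mask_
    hist0 = weight_histogram(est.coef_init_, cfg.histogram_source, cfg.n_bins, columns=columns)
    hist1 = weight_histogram(est.coef_, cfg.histogram_source, cfg.n_bins, columns=columns)
    modes0 = count_modes(hist0, cfg.smooth_window, cfg.min_prominence_frac)
    modes1 = count_modes(hist1, cfg.smooth_window, cfg.min_prominence_frac)

    # branch-fraction (q/r/p) trajectory from the stored weight snapshots
    rows = []
    final_fracs = SubsetFractions(
        np.full(est.coef_.shape[0], np.nan),
        np.full(est.coef_.shape[0], np.nan),
        np.full(est.coef_.shape[0], np.nan),
    )
    if cfg.t_len > 0 and cfg.store_history:
        th1, th2 = _diagnostic_thresholds(cfg, est, est.coef_init_, seq.frames[0])
        for t, x in enumerate(seq.frames):
            w_t = est.coef_history_[t]
            fr = subset_fractions(_diagnostic_coincidence(est, w_t, x), x, th1, th2)
            rows.append(
                {"step": t, "q": _nanmean(fr.q), "r": _nanmean(fr.r), "p": _nanmean(fr.p)}
            )
            final_fracs = fr
    qrp = pd.DataFrame(rows, columns=["step", "q", "r", "p"])

    frames = seq.frames if cfg.t_len > 0 else ps.matrix[:1]
    outputs0 = (frames.astype(float) @ est.coef_init_.T >= est.eta_).astype(np.uint8)
    outputs1 = est.predict(frames)
    sims = weight_input_similarity(est.coef_, ps)

    resolved = cfg.to_dict()
    resolved["ones_count"] = ones
    resolved["eta_resolved"] = est.eta_
    if hasattr(est, "theta1_"):
        resolved["theta1_resolved"] = est.theta1_
        resolved["theta2_resolved"] = est.theta2_

    result = ExperimentResult(
        config=resolved,
        pattern_set=ps,
        sequence=seq,
        estimator=est,
        hist_initial=hist0,
        hist_final=hist1,
        modes_initial=modes0,
        modes_final=modes1,
        qrp=qrp,
        qrp_final=final_fracs,
        outputs_initial=outputs0,
        outputs_final=outputs1,
        similarity_assignments=sims.assignment_counts,
    )
    if cfg.outdir is not None:
        write_result(Path(cfg.outdir), result)
    return result


def write_result(outdir: Path, result: ExperimentResult) -> None:
    """Write the machine-readable report files for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    (outdir / "summary.json").write_text(json.dumps(result.summary(), indent=2, sort_keys=True))
    (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    save_pattern_set(outdir / "patterns.txt", result.pattern_set)
    save_sequence(outdir / "sequence.txt", result.sequence)
    for name, hist in (("t0", result.hist_initial), (f"t{cfg['t_len']}", result.hist_final)):
        pd.DataFrame(
            {"bin_left": hist.bin_edges[:-1], "bin_right": hist.bin_edges[1:], "count": hist.counts}
        ).to_csv(outdir / f"histogram_{name}.csv", index=False)
    modes = {
        "initial": _mode_dict(result.modes_initial),
        "final": _mode_dict(result.modes_final),
    }
    (outdir / "modes.json").write_text(json.dumps(modes, indent=2, sort_keys=True))
    result.qrp.to_csv(outdir / "qrp.csv", index=False)
    np.savetxt(outdir / "outputs.txt", result.outputs_final, fmt="%d")


def _mode_dict(mr: ModeReport) -> dict:
    return {
        "n_modes": mr.n_modes,
        "locations": [round(float(v), 6) for v in mr.mode_locations],
        "prominences": [round(float(v), 6) for v in mr.prominences],
        "smooth_window": mr.smooth_window,
        "min_prominence_frac": mr.min_prominence_frac,
    }


#: Weight increment used by the completion/discrimination readout.  The
#: output-level contrast between the rules exists only when the increment is
#: small relative to the initial weight spread (threshold-crossing jitter
#: keeps accumulating over the steps); large increments freeze the branch
#: classification after the first step and the contrast washes out.
DISCRIMINATION_DW = 0.05


def run_completion_discrimination(
    base_cfg: ExperimentConfig,
    rule: Literal["heblr", "stlr"],
    dw: float | None = DISCRIMINATION_DW,
) -> dict:
    """Completion/discrimination measurement for one rule.

    Trains ``k`` replicate networks with *shared* initial weights, one per
    same-context sequence built from each pattern A_i, reads out each
    network's response to its training frame, and returns the pairwise
    Hamming-distance matrix of those outputs.  Small distances mean the
    similar sequences collapsed onto one representation (completion), large
    distances mean they were separated (discrimination).

    ``dw`` defaults to :data:`DISCRIMINATION_DW` rather than the base
    config's increment: this readout lives in the small-increment regime
    (see the methods note); pass ``None`` to inherit ``base_cfg.dw``.
    """
    if dw is None:
        dw = base_cfg.dw
    cfg = dataclasses.replace(base_cfg, rule=rule, context="same", dw=dw, outdir=None)
    ones = cfg.resolved_ones_count()
    ps = generate_pattern_set(cfg.n, cfg.k, cfg.hd, ones, seed=cfg.seed)
    outputs = []
    for i in range(cfg.k):
        cfg_i = dataclasses.replace(cfg, same_pattern_index=i, store_history=False)
        seq = make_same_context_sequence(ps[i], t_len=cfg.t_len)
        est = build_estimator(cfg_i)  # random_state = seed+2 for every replicate
        est.fit(seq.frames)
        outputs.append(est.predict(ps[i][None, :])[0])
    outputs = np.asarray(outputs)
    dist = output_discrimination_matrix(outputs)
    return {
        "rule": rule,
        "outputs": outputs,
        "distance_matrix": dist,
        "mean_pairwise_distance": mean_offdiagonal(dist),
    }


def run_grid_and_report(base_cfg: ExperimentConfig, outdir=None) -> dict:
    """Run the 2×2 rule × context grid plus the discrimination contrast.

    All four conditions share the pattern set and initial weights (same
    ``seed``).  A failing condition is recorded as a structured error and
    does not abort the others.  Returns (and optionally writes) the summary.
    """
    outdir = Path(outdir) if outdir is not None else None
    summary: dict = {"seed": base_cfg.seed, "conditions": {}, "errors": {}}
    results = {}
    for rule, context in GRID_CONDITIONS:
        name = f"{rule}_{context}"
        cond_dir = str(outdir / name) if outdir is not None else None
        cfg = dataclasses.replace(base_cfg, rule=rule, context=context, outdir=cond_dir)
        try:
            res = run_experiment(cfg)
        except (ValueError, TypeError) as exc:
            summary["errors"][name] = {"type": type(exc).__name__, "message": str(exc)}
            continue
        results[name] = res
        summary["conditions"][name] = res.summary()
    try:
        disc = {
            rule: run_completion_discrimination(base_cfg, rule) for rule in ("heblr", "stlr")
        }
        summary["discrimination"] = {
            rule: {
                "mean_pairwise_output_distance": d["mean_pairwise_distance"],
                "distance_matrix": d["distance_matrix"].tolist(),
            }
            for rule, d in disc.items()
        }
    except (ValueError, TypeError) as exc:
        summary["errors"]["discrimination"] = {
            "type": type(exc).__name__,
            "message": str(exc),
        }
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    summary["_results"] = results
    return summary
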