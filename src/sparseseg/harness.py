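"""Experimental harness: exhaustive missing-sequence simulation, paired
nonparametric model comparison, and the end-to-end experiment driver.

The evaluation protocol mirrors a missing-modality robustness study: every
model is evaluated on every test subject under all 2^3 = 8 combinations of
simulated missing secondary sequences (including the empty pattern), Dice
scores of seed-matched model pairs are compared per pattern with two-sided
Wilcoxon signed rank tests, and a *single* Bonferroni correction over the
whole family of computed p-values controls multiplicity.  The family size is
reported explicitly in every output.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import CHANNEL_NAMES, SECONDARY_CHANNELS, Subject
from .metrics import evaluate_pair
from .net import NetConfig, TrainConfig, DualPathwayNet, predict, train
from .normalize import fit_histogram_model, normalize_cohort
from .synth import PhantomConfig, generate_cohort_subjects

__all__ = [
    "MissingPattern", "all_missing_patterns", "apply_missing_pattern",
    "evaluate_model_under_patterns", "wilcoxon_signed_rank", "WilcoxonResult",
    "bonferroni_adjust", "ExperimentConfig", "run_experiment",
]


@dataclasses.dataclass(frozen=True)
class MissingPattern:
    """A subset of secondary channels simulated as absent (zero-filled)."""

    zeroed: frozenset

    def __post_init__(self):
        bad = set(self.zeroed) - set(SECONDARY_CHANNELS)
        if bad:
            raise ValueError(f"unknown or primary channels in pattern: {sorted(bad)}")

    @property
    def label(self) -> str:
        if not self.zeroed:
            return "none"
        return "+".join(c for c in CHANNEL_NAMES if c in self.zeroed)

    @classmethod
    def from_label(cls, label: str) -> "MissingPattern":
        if label in ("", "none"):
            return cls(frozenset())
        return cls(frozenset(label.split("+")))


def all_missing_patterns() -> list[MissingPattern]:
    """All 8 subsets of the secondary channels, the empty pattern first."""
    out = []
    for r in range(len(SECONDARY_CHANNELS) + 1):
        for combo in itertools.combinations(SECONDARY_CHANNELS, r):
            out.append(MissingPattern(frozenset(combo)))
    return out


def apply_missing_pattern(subject: Subject, pattern: MissingPattern) -> Subject:
    """Zero the pattern's channels and flag them unavailable (pure function).

    Works on raw or normalized subjects alike: zeros survive normalization by
    the zero-preservation invariant.  Idempotent; the input is not modified.
    """
    out = subject.copy()
    for name in pattern.zeroed:
        idx = CHANNEL_NAMES.index(name)
        out.channels[idx] = 0.0
        out.available[idx] = False
    return out


def evaluate_model_under_patterns(model: DualPathwayNet,
                                  subjects: Sequence[Subject],
                                  patterns: Optional[Sequence[MissingPattern]] = None,
                                  model_id: str = "") -> pd.DataFrame:
    """One metric row per (subject, pattern); 8 x n rows by default.

    Subjects must be normalized with ground-truth masks.  A subject whose
    originally missing channels are not a subset of the simulated pattern is
    flagged ``confounded`` for that pattern (the observed behavior mixes real
    and simulated missingness).
    """
    patterns = list(patterns) if patterns is not None else all_missing_patterns()
    rows = []
    for pattern in patterns:
        for s in subjects:
            if s.mask is None:
                raise ValueError(f"subject {s.subject_id} has no ground truth")
            missing = {CHANNEL_NAMES[i] for i in range(len(CHANNEL_NAMES))
                       if not s.available[i]}
            confounded = not missing <= set(pattern.zeroed)
            pred = predict(model, apply_missing_pattern(s, pattern))
            t = evaluate_pair(s.mask, pred.voxels, spacing=s.spacing)
            flags = list(t.flags) + (["confounded"] if confounded else [])
            rows.append({
                "subject_id": s.subject_id, "model_id": model_id,
                "missing_pattern": pattern.label,
                "dice": t.dice, "sensitivity": t.sensitivity, "hd95": t.hd95,
                "tp": t.tp, "fp": t.fp, "fn": t.fn, "flags": "|".join(flags),
            })
    return pd.DataFrame(rows)


# -- paired statistics ----------------------------------------------------

@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    p: float
    statistic: float   # W+ = sum of ranks of positive differences
    n: int             # pairs used after zero handling
    method: str        # "exact" or "normal"
    flag: str = ""


def _exact_signed_rank_p(w_plus: float, n: int) -> float:
    """Two-sided p by enumerating the 2^n sign assignments over ranks 1..n.

    Dynamic program over the distribution of W+ (integer ranks, no ties):
    the generating polynomial is prod_r (1 + x^r) / 2^n.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = 2.0 ** n
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum() / total
    p_ge = counts[w:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float],
                         zero_method: str = "wilcox",
                         exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed rank test on paired scores.

    Differences ``a - b`` equal to zero are dropped (``zero_method="wilcox"``,
    the classic treatment) or kept for ranking and then discarded from the
    statistic (``"pratt"``).  With no tied absolute differences and
    ``n <= exact_max_n`` the exact null distribution is enumerated; otherwise
    a normal approximation with continuity and tie correction is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return WilcoxonResult(p=1.0, statistic=0.0, n=0, method="degenerate",
                              flag="all_differences_zero")

    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = _rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks_all = _rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = len(d)
    if n < 5:
        flag = "n_lt_5"
    else:
        flag = ""
    w_plus = float(ranks[d > 0].sum())

    integer_ranks = np.allclose(ranks, np.round(ranks)) and \
        set(np.round(ranks).astype(int)) == set(range(1, n + 1))
    if n <= exact_max_n and integer_ranks:
        p = _exact_signed_rank_p(w_plus, n)
        return WilcoxonResult(p=p, statistic=w_plus, n=n, method="exact", flag=flag)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(p=1.0, statistic=w_plus, n=n, method="normal",
                              flag="zero_variance")
    z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * 0.5 * math.erfc(max(z, 0.0) / math.sqrt(2.0)))
    return WilcoxonResult(p=p, statistic=w_plus, n=n, method="normal", flag=flag)


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks (ties shared), 1-based."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def bonferroni_adjust(p_values: Sequence[float],
                      n_tests: Optional[int] = None) -> list[float]:
    """Multiply-and-cap over a single family of ``n_tests`` comparisons.

    ``n_tests`` defaults to ``len(p_values)``; pass the full family size when
    adjusting a subset of a larger run.
    """
    p = list(p_values)
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p-value {v} outside [0, 1]")
    m = n_tests if n_tests is not None else len(p)
    return [min(1.0, v * m) for v in p]


# -- experiment driver ----------------------------------------------------

@dataclasses.dataclass
class ExperimentConfig:
    """End-to-end run: phantom cohort -> model grid -> patterns -> statistics."""

    seed: int = 0
    n_train: int = 40
    n_val: int = 2
    n_test: int = 20
    phantom: Optional[PhantomConfig] = None   # seed is overridden by `seed`
    net_preset: str = "tiny"
    iterations: int = 500
    sparsify_p: float = 0.2
    complete_test: bool = True
    # Train both models on complete imaging, so that zero-filled channels
    # reach the plain model only through the sparsified augmentation — the
    # configuration in which the with/without comparison isolates the method.
    complete_train: bool = True
    # Optional grid over training-data variants, e.g. ("complete", "all"):
    # "complete" restricts training to complete-imaging subjects, "all" also
    # includes subjects with naturally missing channels.  Overrides
    # complete_train when set; model ids get a variant suffix.
    data_variants: Optional[tuple] = None
    out_dir: Optional[str] = None

    def net_config(self) -> NetConfig:
        return NetConfig.tiny() if self.net_preset == "tiny" else NetConfig.full()

    def train_config(self) -> TrainConfig:
        if self.net_preset == "tiny":
            tc = TrainConfig.tiny(seed=self.seed + 1, iterations=self.iterations)
        else:
            tc = TrainConfig.full(seed=self.seed + 1)
        return dataclasses.replace(tc, sparsify_p=self.sparsify_p)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = raw.pop("phantom", None)
        cfg = cls(**raw)
        if phantom:
            cfg.phantom = PhantomConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in phantom.items()})
        return cfg


def run_experiment(config: ExperimentConfig) -> dict:
    """Train a seed-matched {plain, sparsified} pair and compare them.

    Returns a dict with the metric table, per-pattern medians, and paired
    comparisons (single-family Bonferroni).  When ``config.out_dir`` is set,
    writes ``metrics.csv``, ``medians.csv``, ``comparisons.csv``, the
    training logs, and a per-pattern Dice box plot.
    """
    phantom = config.phantom or PhantomConfig()
    phantom = dataclasses.replace(phantom, seed=config.seed)

    variants = config.data_variants or \
        (("complete",) if config.complete_train else ("all",))
    suffix = len(variants) > 1

    test_start = config.n_train + config.n_val
    test_subjects = generate_cohort_subjects(
        phantom, config.n_test, start_seed=test_start,
        force_complete=config.complete_test)

    net_cfg = config.net_config()
    train_cfg = config.train_config()

    models, logs, tables = {}, {}, []
    hist = None
    for variant in variants:
        train_subjects = generate_cohort_subjects(
            phantom, config.n_train, start_seed=0,
            force_complete=(variant == "complete"))
        hist = fit_histogram_model(train_subjects)
        train_norm = normalize_cohort(train_subjects, hist)
        test_norm = normalize_cohort(test_subjects, hist)
        for sparsified, base_id in ((False, "plain"), (True, "sparsified")):
            model_id = f"{base_id}-{variant}" if suffix else base_id
            model, log = train(train_norm, net_cfg, train_cfg,
                               sparsified=sparsified)
            models[model_id] = model
            logs[model_id] = log
            tables.append(evaluate_model_under_patterns(model, test_norm,
                                                        model_id=model_id))
    metrics_df = pd.concat(tables, ignore_index=True)

    patterns = [p.label for p in all_missing_patterns()]
    medians = (metrics_df.groupby(["model_id", "missing_pattern"])["dice"]
               .median().rename("median_dice").reset_index())

    comparisons = []
    for variant in variants:
        id_sp = f"sparsified-{variant}" if suffix else "sparsified"
        id_pl = f"plain-{variant}" if suffix else "plain"
        for label in patterns:
            sub = metrics_df[metrics_df["missing_pattern"] == label]
            a = sub[sub["model_id"] == id_sp].sort_values("subject_id")
            b = sub[sub["model_id"] == id_pl].sort_values("subject_id")
            if not (a["subject_id"].values == b["subject_id"].values).all():
                raise RuntimeError(
                    "pairing integrity violated: subject order differs")
            res = wilcoxon_signed_rank(a["dice"].values, b["dice"].values)
            comparisons.append({
                "model_a": id_sp, "model_b": id_pl,
                "missing_pattern": label, "n": res.n,
                "median_diff": float(np.median(a["dice"].values
                                               - b["dice"].values)),
                "w_statistic": res.statistic, "p_raw": res.p,
                "method": res.method, "flags": res.flag,
            })
    comp_df = pd.DataFrame(comparisons)
    n_family = len(comp_df)
    comp_df["n_tests"] = n_family
    comp_df["p_adjusted"] = bonferroni_adjust(comp_df["p_raw"].tolist(), n_family)
    comp_df["significant"] = comp_df["p_adjusted"] < 0.05

    result = {"metrics": metrics_df, "medians": medians, "comparisons": comp_df,
              "models": models, "logs": logs, "histogram_model": hist,
              "n_tests": n_family}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out / "metrics.csv", index=False)
        medians.to_csv(out / "medians.csv", index=False)
        comp_df.to_csv(out / "comparisons.csv", index=False)
        for mid, log in logs.items():
            log.to_csv(out / f"training_log_{mid}.csv", index=False)
        hist.to_json(out / "histogram_model.json")
        _plot_patterns(metrics_df, out / "dice_by_missing_pattern.png")
    return result


def _plot_patterns(metrics_df: pd.DataFrame, path) -> None:
    """Per-pattern Dice box plots, sparsified vs plain, side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    patterns = [p.label for p in all_missing_patterns()]
    model_ids = sorted(metrics_df["model_id"].unique())
    fig, ax = plt.subplots(figsize=(1.4 * len(patterns) + 2, 4.5))
    width = 0.7 / max(2, len(model_ids))
    cycle = ["tab:blue", "tab:orange", "tab:green", "tab:red"]
    colors = {mid: cycle[i % len(cycle)] for i, mid in enumerate(model_ids)}
    for k, mid in enumerate(model_ids):
        data = [metrics_df[(metrics_df["model_id"] == mid)
                           & (metrics_df["missing_pattern"] == lab)]["dice"].values
                for lab in patterns]
        pos = np.arange(len(patterns)) + (k - (len(model_ids) - 1) / 2) * width
        bp = ax.boxplot(data, positions=pos, widths=width * 0.9,
                        patch_artist=True, manage_ticks=False)
        for box in bp["boxes"]:
            box.set_facecolor(colors[mid])
            box.set_alpha(0.6)
    ax.set_xticks(np.arange(len(patterns)))
    ax.set_xticklabels(patterns, rotation=30, ha="right")
    ax.set_ylabel("Dice")
    ax.set_xlabel("simulated missing sequences")
    ax.set_ylim(-0.02, 1.02)
    handles = [plt.Rectangle((0, 0), 1, 1, fc=c, alpha=0.6)
               for c in colors.values()]
    ax.legend(handles, list(colors.keys()), loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
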