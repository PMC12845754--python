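"""Experiment orchestration: pre-training -> registration -> verification.

The three stages mirror how an EEG biometric enrollment system operates:

1. *Pre-training*: one 4-class intent model per subject (their three task
   conditions against pooled other-subject negatives).  Each model's
   channel-attention weights yield a frozen per-subject electrode ranking.
2. *Registration*: a single closed-set identity classifier over all
   subjects, fed windows assembled according to an electrode-selection
   strategy (subject-specific ranking, a shared data-driven global set, or
   a fixed montage).
3. *Verification*: identification posteriors on held-out runs are expanded
   into genuine/impostor trials for FAR/FRR/EER, and each identified
   window is routed to that subject's pre-trained model for intent
   recognition (intent is only evaluated after identification).

Outputs (ranking CSVs, metric JSONs) contain a configuration hash and the
seed but no timestamps, so a re-run with the same configuration is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone import ChannelRanking, IntentBackbone, rank_and_select
from .cma import PersonIdentifier, assemble_input
from .data import (
    PRETRAINING_TEMPLATE,
    REGISTRATION_TEMPLATE,
    SplitTemplate,
    Run,
    check_no_leakage,
    make_folds,
    relabel_for_pretraining,
    segment_run,
)
from .metrics import enumerate_trials, error_curve_and_eer, identification_metrics
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("aesmbe")

__all__ = [
    "ExperimentConfig",
    "StageReport",
    "common_global_selection",
    "default_fixed_montage",
    "run_pretraining_stage",
    "run_registration_stage",
    "run_verification_stage",
    "run_full_pipeline",
    "save_rankings",
    "load_rankings",
]

STRATEGIES = ("fixed", "common_global", "subject_specific")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    budget: int = 4
    strategy: str = "subject_specific"
    common_k: int | None = None  # top-k per subject for the global count
    fixed_montage: tuple | None = None
    pretraining_template: SplitTemplate = field(default=PRETRAINING_TEMPLATE)
    registration_template: SplitTemplate = field(default=REGISTRATION_TEMPLATE)
    backbone: dict = field(default_factory=dict)  # IntentBackbone kwargs
    cma: dict = field(default_factory=dict)  # PersonIdentifier kwargs
    n_folds: int | None = None  # limit folds evaluated (None = all)
    ranking_refit: bool = True  # extract rankings from an all-runs refit
    repetitions: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.strategy == "fixed" and self.fixed_montage is not None:
            if len(self.fixed_montage) != self.budget:
                raise ValueError("fixed montage length must equal the budget")
        if self.common_k is not None and self.common_k < 1:
            raise ValueError("common_k must be >= 1")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["pretraining_template"] = {
            "stage": self.pretraining_template.stage,
            "folds": [list(map(list, f)) for f in self.pretraining_template.folds],
        }
        d["registration_template"] = {
            "stage": self.registration_template.stage,
            "folds": [list(map(list, f)) for f in self.registration_template.folds],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        for key in ("pretraining_template", "registration_template"):
            if key in d and isinstance(d[key], dict):
                d[key] = SplitTemplate(
                    stage=d[key]["stage"],
                    folds=tuple(
                        (tuple(f[0]), tuple(f[1])) for f in d[key]["folds"]
                    ),
                )
        if d.get("fixed_montage") is not None:
            d["fixed_montage"] = tuple(d["fixed_montage"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StageReport:
    """Aggregated metrics for one stage run."""

    stage: str
    config_hash: str
    seed: int
    per_fold: list = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "StageReport":
        return cls(**json.loads(Path(path).read_text()))


# ----------------------------------------------------------- selection rules
def default_fixed_montage(n_channels: int, budget: int) -> list[int]:
    """Evenly spaced electrode subset over the index range (documented
    stand-in for a hand-picked montage; real layouts go in the config)."""
    return sorted(
        int(round(i)) for i in np.linspace(0, n_channels - 1, budget)
    )


def common_global_selection(
    rankings: dict[int, ChannelRanking], k: int, budget: int
) -> list[int]:
    """One shared electrode list: top-``budget`` by top-``k`` membership.

    Counts, over all subjects, how often each channel appears in that
    subject's top-``k``; the ``budget`` most frequent channels win, ties
    broken by ascending channel index.  Returned in descending-frequency
    order.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    n_channels = len(next(iter(rankings.values())).order)
    if not 1 <= k <= n_channels:
        raise ValueError(f"k={k} out of range [1, {n_channels}]")
    counts = np.zeros(n_channels, dtype=int)
    for r in rankings.values():
        counts[list(r.order[:k])] += 1
    order = np.lexsort((np.arange(n_channels), -counts))
    return [int(c) for c in order[:budget]]


def _montage_ranking(montage: list[int], n_channels: int) -> ChannelRanking:
    """Wrap an explicit electrode list as a ranking (for assemble_input)."""
    scores = np.zeros(n_channels)
    scores[list(montage)] = np.arange(len(montage), 0, -1)
    ranking, _ = rank_and_select(scores, n_channels, subject_id=-1)
    return ranking


def resolve_selection(
    config: ExperimentConfig,
    rankings: dict[int, ChannelRanking] | None,
    subjects: list[int],
    rng: np.random.Generator | None = None,
) -> dict[int, ChannelRanking]:
    """Per-subject ranking to assemble inputs from, per the strategy."""
    c = config.synthetic.n_channels
    if config.strategy == "subject_specific":
        if rankings is None:
            raise ValueError(
                "strategy=subject_specific requires pre-training rankings"
            )
        missing = [s for s in subjects if s not in rankings]
        if missing:
            raise ValueError(f"subjects without rankings: {missing}")
        return {s: rankings[s] for s in subjects}
    if config.strategy == "common_global":
        if rankings is None:
            raise ValueError("strategy=common_global requires pre-training rankings")
        k = config.common_k or config.budget
        montage = common_global_selection(rankings, k, config.budget)
        shared = _montage_ranking(montage, c)
        return {s: shared for s in subjects}
    # fixed montage: explicit list from the config, else the documented
    # evenly spaced default (random montages for baseline comparisons are
    # produced by the caller and passed as fixed_montage)
    if config.fixed_montage is not None:
        montage = list(config.fixed_montage)
    else:
        montage = default_fixed_montage(c, config.budget)
    shared = _montage_ranking(montage, c)
    return {s: shared for s in subjects}


# ------------------------------------------------------------------- stages
def _fold_windows(runs, template, n_folds, H=160):
    folds = make_folds(runs, template, H=H)
    if n_folds is not None:
        folds = folds[:n_folds]
    for train_w, test_w in folds:
        leak = check_no_leakage(train_w, test_w)
        if leak:
            raise RuntimeError(f"run leakage detected across fold sides: {leak}")
    return folds


def run_pretraining_stage(
    config: ExperimentConfig, runs: list[Run] | None = None
) -> tuple[dict[int, ChannelRanking], StageReport, dict[int, IntentBackbone]]:
    """Train one intent model per subject; freeze one ranking per subject.

    Fold models provide the held-out 4-class intent accuracies.  The
    frozen ranking is extracted from a refit on all of the subject's
    enrollment runs (``ranking_refit=True``, default) — the fold hold-out
    exists to measure intent accuracy without leakage, while the ranking
    benefits from every run; with ``ranking_refit=False`` the ranking uses
    channel-importance scores averaged over the fold models instead.

    Returns the frozen rankings, the stage report, and the per-subject
    intent models that the verification stage routes identified windows
    to (the refit model, or the last fold model without refit).
    """
    if runs is None:
        runs = generate_dataset(config.synthetic)
    subjects = sorted({r.subject_id for r in runs})
    if len(subjects) < 2:
        raise ValueError("pre-training needs >= 2 subjects (negative class)")
    report = StageReport(
        stage="pretraining", config_hash=config.config_hash(), seed=config.seed
    )
    rankings: dict[int, ChannelRanking] = {}
    backbones: dict[int, IntentBackbone] = {}
    per_subject_acc: dict[int, float] = {}
    all_windows = (
        [w for r in runs for w in segment_run(r)] if config.ranking_refit else None
    )
    for target in subjects:
        folds = _fold_windows(runs, config.pretraining_template, config.n_folds)
        scores_acc = []
        fold_accs = []
        for fi, (train_w, test_w) in enumerate(folds):
            tr_w, tr_y = relabel_for_pretraining(train_w, target, seed=config.seed)
            te_w, te_y = relabel_for_pretraining(test_w, target, seed=config.seed)
            est = IntentBackbone(**{"seed": config.seed, **config.backbone})
            est.fit(np.stack([w.data for w in tr_w]), tr_y)
            acc = float(
                np.mean(est.predict(np.stack([w.data for w in te_w])) == te_y)
            )
            fold_accs.append(acc)
            scores_acc.append(est.channel_scores())
            report.per_fold.append(
                {"subject": target, "fold": fi, "intent_accuracy": acc}
            )
            logger.info("pretrain subject=%s fold=%d acc=%.3f", target, fi, acc)
        if config.ranking_refit:
            rf_w, rf_y = relabel_for_pretraining(all_windows, target, seed=config.seed)
            refit = IntentBackbone(**{"seed": config.seed, **config.backbone})
            refit.fit(np.stack([w.data for w in rf_w]), rf_y)
            scores = refit.channel_scores()
            backbones[target] = refit
        else:
            scores = np.mean(scores_acc, axis=0)
            backbones[target] = est
        ranking, _ = rank_and_select(scores, len(scores), subject_id=target)
        rankings[target] = ranking
        per_subject_acc[target] = float(np.mean(fold_accs))
    accs = np.array(list(per_subject_acc.values()))
    report.aggregate = {
        "average_intent_accuracy": float(accs.mean()),
        "best_subject_accuracy": float(accs.max()),
        "per_subject_accuracy": {str(s): a for s, a in per_subject_acc.items()},
    }
    return rankings, report, backbones


def run_registration_stage(
    config: ExperimentConfig,
    runs: list[Run] | None = None,
    rankings: dict[int, ChannelRanking] | None = None,
) -> tuple[PersonIdentifier, StageReport, dict]:
    """Train the unified identity classifier under the selection strategy.

    Returns the model fitted on the last fold, the report over
    ``n_folds x repetitions`` fits, and the held-out data of the last fold
    (for the verification stage).
    """
    if runs is None:
        runs = generate_dataset(config.synthetic)
    subjects = sorted({r.subject_id for r in runs})
    selection = resolve_selection(config, rankings, subjects)
    report = StageReport(
        stage="registration", config_hash=config.config_hash(), seed=config.seed
    )
    folds = _fold_windows(runs, config.registration_template, config.n_folds)
    est = None
    last_heldout = None
    for rep in range(config.repetitions):
        for fi, (train_w, test_w) in enumerate(folds):
            Xtr = np.stack(
                [assemble_input(w.data, selection[w.subject_id], config.budget)
                 for w in train_w]
            )
            ytr = np.array([w.subject_id for w in train_w])
            Xte = np.stack(
                [assemble_input(w.data, selection[w.subject_id], config.budget)
                 for w in test_w]
            )
            yte = np.array([w.subject_id for w in test_w])
            est = PersonIdentifier(
                **{"seed": config.seed + rep, **config.cma}
            )
            est.fit(Xtr, ytr)
            m = identification_metrics(est.predict(Xte), yte)
            report.per_fold.append({"repetition": rep, "fold": fi, **m})
            logger.info(
                "register rep=%d fold=%d acc=%.3f", rep, fi, m["accuracy"]
            )
            last_heldout = (Xte, yte, test_w)
    accs = [e["accuracy"] for e in report.per_fold]
    report.aggregate = {
        "accuracy": float(np.mean(accs)),
        "precision_macro": float(np.mean([e["precision_macro"] for e in report.per_fold])),
        "recall_macro": float(np.mean([e["recall_macro"] for e in report.per_fold])),
        "n_entries": len(report.per_fold),
    }
    return est, report, {"heldout": last_heldout, "selection": selection}


def run_verification_stage(
    config: ExperimentConfig,
    identifier: PersonIdentifier,
    heldout: tuple,
    backbones: dict[int, IntentBackbone] | None = None,
) -> StageReport:
    """Verification metrics (and optional routed intent recognition).

    ``heldout`` is (assembled windows, identity labels, Window objects)
    from the registration stage.  Posteriors are expanded into all-claims
    trials; after identification, each window may be routed to the
    predicted subject's pre-trained intent model.
    """
    if identifier is None or not hasattr(identifier, "net_"):
        raise ValueError("verification requires a fitted registration model")
    Xte, yte, test_w = heldout
    posteriors = identifier.predict_proba(Xte)
    lookup = {c: i for i, c in enumerate(identifier.classes_)}
    labels_idx = np.array([lookup[v] for v in yte])
    trials = enumerate_trials(posteriors, labels_idx)
    curve = error_curve_and_eer(trials)
    ident = identification_metrics(posteriors.argmax(axis=1), labels_idx)
    report = StageReport(
        stage="verification", config_hash=config.config_hash(), seed=config.seed
    )
    report.aggregate = {
        "eer": curve.eer,
        "tau_star": curve.tau_star,
        "n_genuine": int(trials.genuine_scores.size),
        "n_impostor": int(trials.impostor_scores.size),
        **ident,
    }
    if backbones is not None:
        predicted = identifier.classes_[posteriors.argmax(axis=1)]
        missing = sorted({int(p) for p in predicted} - set(backbones))
        if missing:
            raise ValueError(
                f"no pre-trained intent model for predicted identities {missing}"
            )
        correct = 0
        total = 0
        for w, pred in zip(test_w, predicted):
            if pred != w.subject_id:
                continue  # intent only evaluated after correct identification
            est = backbones[int(pred)]
            intent = est.predict(w.data[None])[0]
            correct += int(intent == w.task)
            total += 1
        report.aggregate["intent_accuracy_after_identification"] = (
            float(correct / total) if total else float("nan")
        )
        report.aggregate["n_intent_evaluated"] = total
    return report


def run_full_pipeline(config: ExperimentConfig, out_dir=None) -> dict:
    """Pre-training, registration and verification on one synthetic dataset."""
    runs = generate_dataset(config.synthetic)
    rankings, pre_report, backbones = run_pretraining_stage(config, runs)
    identifier, reg_report, extras = run_registration_stage(
        config, runs, rankings
    )
    ver_report = run_verification_stage(
        config, identifier, extras["heldout"], backbones=backbones
    )
    result = {
        "rankings": rankings,
        "pretraining": pre_report,
        "registration": reg_report,
        "verification": ver_report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_rankings(rankings, out / "rankings")
        pre_report.to_json(out / "pretraining.json")
        reg_report.to_json(out / "registration.json")
        ver_report.to_json(out / "verification.json")
    return result


# -------------------------------------------------------------- persistence
def save_rankings(rankings: dict[int, ChannelRanking], out_dir) -> Path:
    """One CSV per subject (1-based electrode numbering) plus a JSON dump."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = {}
    for s, r in sorted(rankings.items()):
        lines = ["subject_id,channel_1based,score,rank"]
        for rank_pos, ch in enumerate(r.order, start=1):
            lines.append(f"{s},{ch + 1},{r.scores[ch]:.12g},{rank_pos}")
        (out / f"subject_{s:03d}.csv").write_text("\n".join(lines) + "\n")
        blob[str(s)] = {"scores": list(r.scores), "order": list(r.order)}
    (out / "rankings.json").write_text(json.dumps(blob, indent=1, sort_keys=True))
    return out


def load_rankings(in_dir) -> dict[int, ChannelRanking]:
    blob = json.loads((Path(in_dir) / "rankings.json").read_text())
    out = {}
    for s, d in blob.items():
        out[int(s)] = ChannelRanking(
            subject_id=int(s),
            scores=tuple(d["scores"]),
            order=tuple(d["order"]),
        )
    return out
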