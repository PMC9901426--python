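"""Scoring predictions against keyword-derived ground truth.

Per-genome and pooled sensitivity/specificity/precision, ROC curves with
trapezoidal AUC (equal to the Mann-Whitney concordance probability with
ties counted half), distribution summaries in the style of the
training-size experiment, and the stratified subsampling experiment
itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from tailhmm import hmm_core
from tailhmm.hmm_core import NONTAIL, TAIL, TailHmm


@dataclass
class EvalResult:
    tpr: float
    fpr: float
    precision: float
    auc: float
    roc_points: list[tuple[float, float]]
    n_pos: int
    n_neg: int


def confusion(
    calls: Sequence[str], truth: Sequence[str]
) -> tuple[int, int, int, int, float, float, float]:
    """2x2 confusion at a fixed operating point.

    Returns (tp, fp, tn, fn, tpr, fpr, precision); precision is NaN when
    nothing is predicted positive.
    """
    if len(calls) != len(truth):
        raise ValueError(f"length mismatch: {len(calls)} calls vs {len(truth)} truth")
    tp = sum(1 for c, t in zip(calls, truth) if c == TAIL and t == TAIL)
    fp = sum(1 for c, t in zip(calls, truth) if c == TAIL and t == NONTAIL)
    tn = sum(1 for c, t in zip(calls, truth) if c == NONTAIL and t == NONTAIL)
    fn = sum(1 for c, t in zip(calls, truth) if c == NONTAIL and t == TAIL)
    tpr = tp / (tp + fn) if tp + fn else math.nan
    fpr = fp / (fp + tn) if fp + tn else math.nan
    precision = tp / (tp + fp) if tp + fp else math.nan
    return tp, fp, tn, fn, tpr, fpr, precision


def roc_auc(scores: Sequence[float], truth: Sequence[str]) -> EvalResult:
    """ROC by sweeping all distinct score thresholds; AUC by trapezoid.

    The trapezoidal integral over the full threshold sweep equals the
    probability that a random positive outscores a random negative, with
    ties counted one half.
    """
    if len(scores) != len(truth):
        raise ValueError("scores and truth differ in length")
    y = np.array([1 if t == TAIL else 0 for t in truth])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    # operating stats at the default 0.5 threshold for convenience
    calls = [TAIL if s >= 0.5 else NONTAIL for s in scores]
    _, _, _, _, tpr05, fpr05, prec05 = confusion(calls, list(truth))
    return EvalResult(
        tpr=tpr05,
        fpr=fpr05,
        precision=prec05,
        auc=auc,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def concordance_auc(scores: Sequence[float], truth: Sequence[str]) -> float:
    """AUC as the Mann-Whitney pairwise concordance probability.

    Independent of the threshold-sweep route; used to cross-check it.
    """
    pos = [s for s, t in zip(scores, truth) if t == TAIL]
    neg = [s for s, t in zip(scores, truth) if t == NONTAIL]
    if not pos or not neg:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def evaluate_genome_set(
    genomes: Mapping[str, Sequence[str]],
    truth: Mapping[str, Sequence[str]],
    model: TailHmm,
    tau: float = hmm_core.DEFAULT_TAU,
) -> dict:
    """Decode every genome, score per genome and pooled.

    ``genomes`` maps genome_id -> ordered observation symbols; ``truth``
    maps genome_id -> TAIL/NONTAIL labels per ordinal.  Genomes whose
    truth contains no tail protein are excluded from the per-genome TPR
    summaries (they have no sensitivity to measure) but still contribute
    to the pooled metrics.
    """
    if not genomes:
        raise ValueError("empty genome set")
    per_genome: dict[str, dict] = {}
    pooled_scores: list[float] = []
    pooled_truth: list[str] = []
    pooled_calls: list[str] = []
    genome_tprs: list[float] = []
    genome_aucs: list[float] = []
    for gid, obs in genomes.items():
        labels = list(truth[gid])
        track = hmm_core.call_tails(
            hmm_core.posterior_decode(model, obs, genome_id=gid), tau
        )
        scores = track.posteriors.tolist()
        pooled_scores.extend(scores)
        pooled_truth.extend(labels)
        pooled_calls.extend(track.calls)
        tp, fp, tn, fn, tpr, fpr, prec = confusion(track.calls, labels)
        entry = {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
                 "tpr": tpr, "fpr": fpr, "precision": prec, "auc": math.nan}
        n_pos = labels.count(TAIL)
        if n_pos and n_pos < len(labels):
            entry["auc"] = roc_auc(scores, labels).auc
            genome_aucs.append(entry["auc"])
        if n_pos:
            genome_tprs.append(tpr)
        per_genome[gid] = entry

    pooled = roc_auc(pooled_scores, pooled_truth)
    tp, fp, tn, fn, tpr, fpr, prec = confusion(pooled_calls, pooled_truth)
    pooled.tpr, pooled.fpr, pooled.precision = tpr, fpr, prec

    def frac(pred) -> float:
        return sum(1 for t in genome_tprs if pred(t)) / len(genome_tprs) if genome_tprs else math.nan

    summary = {
        "n_genomes": len(genomes),
        "n_genomes_with_tail_truth": len(genome_tprs),
        "frac_tpr_eq_1": frac(lambda t: t == 1.0),
        "frac_tpr_gt_0.8": frac(lambda t: t > 0.8),
        "frac_tpr_gt_0.6": frac(lambda t: t > 0.6),
        "median_genome_auc": float(np.median(genome_aucs)) if genome_aucs else math.nan,
    }
    return {"per_genome": per_genome, "pooled": pooled, "summary": summary}


def subsampling_experiment(
    corpus: Mapping[str, Sequence[tuple[str, str]]],
    morphology: Mapping[str, str],
    holdout: Mapping[str, Sequence[tuple[str, str]]],
    sizes: Sequence[int],
    replicates: int,
    seed: int,
    tau: float = hmm_core.DEFAULT_TAU,
) -> list[dict]:
    """Training-set robustness: refit on stratified subsamples.

    For each target size, draw ``replicates`` genome subsamples that
    preserve the morphology proportions of the full corpus, refit the
    HMM, evaluate on the held-out genomes and report the TPR-fraction
    summaries together with the min-max tail-vocabulary (distinct
    tail-state symbol) range across replicates.
    """
    gids = sorted(corpus)
    if any(size > len(gids) for size in sizes):
        raise ValueError("subsample size exceeds corpus size")
    rng = np.random.default_rng(seed)
    by_morph: dict[str, list[str]] = {}
    for gid in gids:
        by_morph.setdefault(morphology.get(gid, "unknown"), []).append(gid)

    ho_obs = {g: [s for s, _ in seq] for g, seq in holdout.items()}
    ho_truth = {g: [st for _, st in seq] for g, seq in holdout.items()}

    rows = []
    for size in sizes:
        vocab_sizes = []
        fracs_1, fracs_08, fracs_06 = [], [], []
        for _ in range(replicates):
            sample: list[str] = []
            for m in sorted(by_morph):
                pool = by_morph[m]
                k = round(size * len(pool) / len(gids))
                k = min(max(k, 0), len(pool))
                sample.extend(rng.choice(pool, size=k, replace=False))
            # pad/trim rounding drift to hit the exact size
            if len(sample) > size:
                sample = list(rng.choice(sample, size=size, replace=False))
            elif len(sample) < size:
                rest = [g for g in gids if g not in set(sample)]
                extra = rng.choice(rest, size=size - len(sample), replace=False)
                sample.extend(extra)
            model = hmm_core.fit([corpus[g] for g in sorted(sample)])
            vocab_sizes.append(
                len({s for g in sample for s, st in corpus[g]
                     if st == TAIL and s != "NOHIT"})
            )
            res = evaluate_genome_set(ho_obs, ho_truth, model, tau)
            fracs_1.append(res["summary"]["frac_tpr_eq_1"])
            fracs_08.append(res["summary"]["frac_tpr_gt_0.8"])
            fracs_06.append(res["summary"]["frac_tpr_gt_0.6"])
        rows.append(
            {
                "size": size,
                "replicates": replicates,
                "seed": seed,
                "frac_tpr_eq_1": float(np.mean(fracs_1)),
                "frac_tpr_gt_0.8": float(np.mean(fracs_08)),
                "frac_tpr_gt_0.6": float(np.mean(fracs_06)),
                "tail_vocab_min": min(vocab_sizes),
                "tail_vocab_max": max(vocab_sizes),
            }
        )
    return rows
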