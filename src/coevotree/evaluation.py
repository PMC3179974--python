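"""Gold standards and coverage-aware performance evaluation.

A gold standard holds positive (interacting) protein pairs and a
constructed negative set: all possible pairs among the proteins involved
in positives, minus the positives themselves.  Its totals P and N are
fixed at construction and never rescaled.

The ROC convention is totals-based: TPR = Tp/P and FPR = Fp/N are always
computed against the *original* dataset totals, irrespective of how many
gold pairs the scoring method could actually evaluate.  A method with
partial coverage therefore produces a curve that terminates before
(1, 1) — curve length doubles as a coverage readout, and the area under
the realized curve penalizes low-coverage methods.  A second, *local* AUC
convention (used by per-protein interactor ranking) evaluates only the
pairs present in a candidate list, via the normalized Mann–Whitney U
statistic with ties counted as 1/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError

__all__ = [
    "GoldStandard",
    "RocCurve",
    "PrCurve",
    "InteractorReport",
    "ExperimentResult",
    "normalize_pair",
    "read_gold_standard",
    "generate_negatives",
    "roc_curve",
    "pr_curve",
    "rank_interactors",
    "run_experiment",
    "write_experiment",
]


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GoldStandard:
    """Positive/negative pair sets with fixed totals P and N."""

    positives: frozenset
    negatives: frozenset
    P: int
    N: int
    label: str = ""

    def __post_init__(self):
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        if self.P != len(self.positives) or self.N != len(self.negatives):
            raise ValueError("totals do not match set sizes")

    def classify(self, pair: tuple[str, str]) -> str | None:
        pair = normalize_pair(*pair)
        if pair in self.positives:
            return "positive"
        if pair in self.negatives:
            return "negative"
        return None


def read_gold_standard(path) -> set[tuple[str, str]]:
    """Read positive pairs from a 2+-column TSV (optional header/label column).

    Pairs are unordered and de-duplicated; a self-pair raises
    :class:`FormatError` naming the offending line.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    pairs: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if lineno == 1 and parts[0].lower() in ("protein_a", "protein1", "id_a"):
            continue
        if len(parts) < 2:
            raise FormatError(f"gold line {lineno}: expected at least 2 columns")
        a, b = parts[0], parts[1]
        if a == b:
            raise FormatError(f"gold line {lineno}: self-pair {a!r}")
        pairs.add(normalize_pair(a, b))
    return pairs


def generate_negatives(positives: Iterable[tuple[str, str]], label: str = "") -> GoldStandard:
    """Build the gold standard: negatives are all pairs among the proteins
    involved in positives that are not themselves positive."""
    pos = {normalize_pair(a, b) for a, b in positives}
    proteins = sorted({p for pair in pos for p in pair})
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins involved in positives")
    negatives = set()
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            pair = (proteins[i], proteins[j])
            if pair not in pos:
                negatives.add(pair)
    return GoldStandard(
        positives=frozenset(pos),
        negatives=frozenset(negatives),
        P=len(pos),
        N=len(negatives),
        label=label,
    )


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Totals-based ROC: points computed against the fixed gold totals."""

    thresholds: list[float]
    points: list[tuple[float, float]]  # (FPR, TPR), starting at (0, 0)
    auc: float
    coverage: float  # fraction of gold pairs that received a score
    counts: list[tuple[int, int]] = field(default_factory=list)  # (Tp, Fp)


@dataclass
class PrCurve:
    points: list[tuple[float, float, float, float]]  # (threshold, precision, recall, F)
    max_f: float


def _labeled_scores(scored_pairs, gold: GoldStandard):
    items = scored_pairs.items() if isinstance(scored_pairs, Mapping) else scored_pairs
    labeled = []
    for pair, score in items:
        cls = gold.classify(tuple(pair))
        if cls is not None:
            labeled.append((float(score), 1 if cls == "positive" else 0))
    labeled.sort(key=lambda t: -t[0])
    return labeled


def _sweep(labeled):
    """Cumulative (threshold, Tp, Fp) at each distinct score, ties as one step."""
    out = []
    tp = fp = 0
    i = 0
    while i < len(labeled):
        thr = labeled[i][0]
        while i < len(labeled) and labeled[i][0] == thr:
            if labeled[i][1]:
                tp += 1
            else:
                fp += 1
            i += 1
        out.append((thr, tp, fp))
    return out


def roc_curve(scored_pairs, gold: GoldStandard) -> RocCurve:
    """ROC against the gold standard's fixed totals.

    Unscored gold pairs count in P and N but never become predictions, so
    low-coverage score lists terminate early; the AUC is the trapezoid
    area under the realized curve.  Raises ``ValueError`` when P or N is
    zero (undefined curve).
    """
    if gold.P == 0 or gold.N == 0:
        raise ValueError("undefined ROC curve: gold standard has P=0 or N=0")
    labeled = _labeled_scores(scored_pairs, gold)
    sweep = _sweep(labeled)
    thresholds = [thr for thr, _, _ in sweep]
    points = [(0.0, 0.0)] + [(fp / gold.N, tp / gold.P) for _, tp, fp in sweep]
    counts = [(0, 0)] + [(tp, fp) for _, tp, fp in sweep]
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    coverage = len(labeled) / (gold.P + gold.N)
    return RocCurve(thresholds=thresholds, points=points, auc=auc, coverage=coverage, counts=counts)


def pr_curve(scored_pairs, gold: GoldStandard) -> PrCurve:
    """Precision/recall/F at each threshold; recall uses the fixed total P."""
    if gold.P == 0 or gold.N == 0:
        raise ValueError("undefined PR curve: gold standard has P=0 or N=0")
    labeled = _labeled_scores(scored_pairs, gold)
    pts = []
    max_f = float("nan")
    for thr, tp, fp in _sweep(labeled):
        if tp + fp == 0:
            continue
        precision = tp / (tp + fp)
        recall = tp / gold.P
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        pts.append((thr, precision, recall, f))
        if not np.isfinite(max_f) or f > max_f:
            max_f = f
    return PrCurve(points=pts, max_f=max_f)


# ---------------------------------------------------------------------------
# per-protein interactor ranking (local AUC convention)
# ---------------------------------------------------------------------------

@dataclass
class InteractorReport:
    protein: str
    candidates: list[tuple[str, float, str | None]]  # (partner, score, label) sorted desc
    n_candidates: int
    n_positives: int
    local_auc: float
    top_partner: str
    top_score: float


def rank_interactors(
    score_table: Mapping[tuple[str, str], float], protein: str, gold: GoldStandard
) -> InteractorReport:
    """Rank a protein's scored partners and measure the local AUC.

    The local AUC is computed over the pairs present in the candidate list
    only (not against the dataset totals): it is the normalized
    Mann-Whitney U, AUC = U / (n+ * n-), with ties counted as 1/2.  NaN if
    the list lacks positives or negatives.
    """
    cands = []
    for pair, score in score_table.items():
        pair = normalize_pair(*pair)
        if protein not in pair:
            continue
        partner = pair[0] if pair[1] == protein else pair[1]
        cands.append((partner, float(score), gold.classify(pair)))
    if not cands:
        raise KeyError(f"protein {protein!r} not present in any scored pair")
    cands.sort(key=lambda t: (-t[1], t[0]))
    labeled = [(s, lab) for _, s, lab in cands if lab is not None]
    pos = [s for s, lab in labeled if lab == "positive"]
    neg = [s for s, lab in labeled if lab == "negative"]
    if pos and neg:
        ranks = stats.rankdata([s for s, _ in labeled])
        pos_ranks = ranks[[i for i, (_, lab) in enumerate(labeled) if lab == "positive"]]
        u = float(pos_ranks.sum()) - len(pos) * (len(pos) + 1) / 2.0
        local_auc = u / (len(pos) * len(neg))
    else:
        local_auc = float("nan")
    return InteractorReport(
        protein=protein,
        candidates=cands,
        n_candidates=len(cands),
        n_positives=len(pos),
        local_auc=local_auc,
        top_partner=cands[0][0],
        top_score=cands[0][1],
    )


# ---------------------------------------------------------------------------
# full experiment grid
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    summary: pd.DataFrame
    cells: dict  # (organism_set_label, method) -> {"roc": RocCurve, "pr": PrCurve, ...}
    manifest: dict


def run_experiment(
    benchmark,
    organism_sets,
    methods: Iterable[str] = ("MT", "PC", "CM"),
    min_common: int = 15,
    p_max: float = 1e-5,
    cm_level: int = 10,
    min_joint: int = 3,
    min_organisms: int = 3,
) -> ExperimentResult:
    """Score and evaluate every (organism set x method) combination.

    For each organism set, the benchmark's family matrices are restricted
    to that set (families falling below ``min_organisms`` retained
    organisms are dropped), all pairs are scored with each method, and
    the scored lists are evaluated against the gold standard with the
    totals-based ROC and F-measure.  Cells with no scorable pairs are
    reported with NaN AUC rather than failing.
    """
    from .coevolution import (
        build_score_matrix,
        context_mirror,
        profile_correlation,
        scored_pairs_from_matrix,
        scored_pairs_from_table,
    )

    methods = [m.upper() for m in methods]
    rows = []
    cells = {}
    for oset in organism_sets:
        label = getattr(oset, "label", None) or str(oset[0])
        genomes = set(getattr(oset, "genomes", None) or oset[1])
        restricted = {}
        for fam, dm in benchmark.family_matrices.items():
            sub = dm.restrict(genomes)
            if sub.n >= min_organisms:
                restricted[fam] = sub
        per_set_scores = {}
        if len(restricted) >= 2:
            sm = build_score_matrix(restricted, min_common=min_common, p_max=p_max)
            if "MT" in methods:
                per_set_scores["MT"] = (scored_pairs_from_matrix(sm), 0)
            if "PC" in methods:
                pc_scores = {}
                prots = sm.proteins
                for i in range(len(prots)):
                    for j in range(i + 1, len(prots)):
                        sc = profile_correlation(sm, prots[i], prots[j], min_joint=min_joint)
                        if sc.evaluable:
                            pc_scores[(prots[i], prots[j])] = sc.r
                per_set_scores["PC"] = (pc_scores, 0)
            if "CM" in methods:
                table = context_mirror(sm, level=cm_level)
                per_set_scores["CM"] = (scored_pairs_from_table(table), cm_level)
        for method in methods:
            scores, level = per_set_scores.get(method, ({}, 0))
            if scores:
                roc = roc_curve(scores, benchmark.gold)
                pr = pr_curve(scores, benchmark.gold)
                auc, max_f, coverage = roc.auc, pr.max_f, roc.coverage
            else:
                roc = pr = None
                auc = max_f = coverage = float("nan")
            rows.append(
                {
                    "organism_set": label,
                    "method": method,
                    "level": level,
                    "auc": auc,
                    "max_f": max_f,
                    "coverage": coverage,
                    "n_scored": len(scores),
                }
            )
            cells[(label, method)] = {"roc": roc, "pr": pr, "scores": scores}
    summary = pd.DataFrame(
        rows, columns=["organism_set", "method", "level", "auc", "max_f", "coverage", "n_scored"]
    )
    manifest = {
        "gold": {"label": benchmark.gold.label, "P": benchmark.gold.P, "N": benchmark.gold.N},
        "methods": methods,
        "min_common": min_common,
        "p_max": p_max,
        "cm_level": cm_level,
        "organism_sets": [getattr(o, "label", None) or str(o[0]) for o in organism_sets],
    }
    return ExperimentResult(summary=summary, cells=cells, manifest=manifest)


def write_experiment(result: ExperimentResult, out_dir) -> Path:
    """One curve TSV per cell, a summary TSV and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6f")
    for (label, method), cell in result.cells.items():
        roc, pr = cell["roc"], cell["pr"]
        path = out / f"curve_{label}_{method}.tsv"
        with open(path, "w") as fh:
            fh.write("threshold\tTp\tFp\tTPR\tFPR\tprecision\trecall\tF\n")
            if roc is None:
                continue
            prmap = {thr: (p, r, f) for thr, p, r, f in pr.points}
            for thr, (tp, fp), (fpr, tpr) in zip(
                roc.thresholds, roc.counts[1:], roc.points[1:]
            ):
                p, r, f = prmap.get(thr, (float("nan"),) * 3)
                fh.write(
                    f"{thr:.6f}\t{tp}\t{fp}\t{tpr:.6f}\t{fpr:.6f}\t{p:.6f}\t{r:.6f}\t{f:.6f}\n"
                )
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
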