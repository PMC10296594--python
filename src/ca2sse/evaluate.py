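"""Evaluation reports and the end-to-end prediction pipeline.

Accuracy is the paper-style hit rate: the fraction of all residues
whose predicted 3-state label matches the truth.  Residues the
classifier cannot label even after post-processing (chains shorter than
one window) count as misses and are reported separately, so the hit
rate stays comparable across methods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .ensemble import EMLClassifier
from .features import compute_feature_matrix
from .postprocess import PostprocessConfig, postprocess
from .subspace import Model2Config, SSESubspaceModel, classify_model1, classify_model2
from .trace import (
    LABELS,
    UNRESOLVED,
    CaTrace,
    ChainRejectionError,
    LabelSequence,
    read_ca_trace,
    read_sse_labels,
    write_predictions,
)

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "evaluate", "classify_trace", "run_pipeline"]


@dataclass
class EvalReport:
    """Confusion matrix (rows observed, columns predicted; order H, E, L)."""

    confusion: np.ndarray
    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    n_total: int
    n_unresolved: int

    def to_dict(self) -> dict:
        return {
            "labels": list(LABELS),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_total": self.n_total,
            "n_unresolved": self.n_unresolved,
        }

    def __str__(self) -> str:
        lines = ["Observed/Predicted\t" + "\t".join(LABELS) + "\tTotal"]
        for i, lab in enumerate(LABELS):
            row = "\t".join(str(int(v)) for v in self.confusion[i])
            lines.append(f"{lab}\t{row}\t{int(self.confusion[i].sum())}")
        lines.append("Accuracy\t{:.2%} ({} residues, {} unresolved)".format(
            self.accuracy, self.n_total, self.n_unresolved))
        for lab in LABELS:
            lines.append("{}\tP={:.3f}\tR={:.3f}\tF1={:.3f}".format(
                lab, self.precision[lab], self.recall[lab], self.f1[lab]))
        return "\n".join(lines)


def evaluate(pred: LabelSequence, truth: LabelSequence) -> EvalReport:
    """Score a prediction against truth labels."""
    if len(pred) != len(truth):
        raise ValueError("prediction and truth have different lengths")
    p = np.asarray(list(pred))
    t = np.asarray(list(truth))
    n = len(t)
    unresolved = int(np.sum(p == UNRESOLVED))
    cm4 = confusion_matrix(t, p, labels=list(LABELS) + [UNRESOLVED])
    cm = cm4[:3, :3]
    assert cm4[:3].sum() == n, "confusion rows must cover all residues"
    hits = int(np.trace(cm))
    prec, rec, f1, _ = precision_recall_fscore_support(
        t, p, labels=list(LABELS), zero_division=0)
    return EvalReport(
        confusion=cm,
        accuracy=hits / n if n else 0.0,
        precision=dict(zip(LABELS, prec.tolist())),
        recall=dict(zip(LABELS, rec.tolist())),
        f1=dict(zip(LABELS, f1.tolist())),
        n_total=n,
        n_unresolved=unresolved,
    )


def classify_trace(trace: CaTrace, method: str,
                   subspace_model: SSESubspaceModel | None = None,
                   eml_model: EMLClassifier | None = None,
                   model2_cfg: Model2Config = Model2Config(),
                   do_postprocess: bool = True,
                   pp_cfg: PostprocessConfig = PostprocessConfig()) -> LabelSequence:
    """Label one trace with the chosen method (model1 | model2 | eml)."""
    fm = compute_feature_matrix(trace)
    if method == "model1":
        labels = classify_model1(trace, subspace_model)
    elif method == "model2":
        labels = classify_model2(trace, subspace_model, model2_cfg)
    elif method == "eml":
        ok = fm.column_valid()
        labs = [UNRESOLVED] * len(trace)
        if ok.any():
            pred = eml_model.predict(fm.values[:, ok].T)
            for idx, lab in zip(np.where(ok)[0], pred):
                labs[idx] = str(lab)
        labels = LabelSequence(labs, provenance="eml")
    else:
        raise ValueError(f"unknown method {method!r}")
    if do_postprocess:
        labels = postprocess(labels, fm, pp_cfg)
    return labels


def run_pipeline(pdb_paths, chain_ids, method: str = "model1",
                 subspace_model: SSESubspaceModel | None = None,
                 eml_model: EMLClassifier | None = None,
                 do_postprocess: bool = True, lenient: bool = False,
                 out_dir=None):
    """Featurize, classify and (when truth is present) evaluate chains.

    Returns ``(per_chain_reports, pooled_report)``; chains rejected by
    the cleaning rules are skipped with a logged reason.  Raises when
    every chain is rejected.
    """
    per_chain = {}
    pooled_pred: list[str] = []
    pooled_truth: list[str] = []
    n_rejected = 0
    for path, chain_id in zip(pdb_paths, chain_ids):
        text = Path(path).read_text()
        chain_key = f"{Path(path).stem}_{chain_id}"
        try:
            trace = read_ca_trace(text, chain_id, lenient=lenient)
        except ChainRejectionError as e:
            logger.warning("skipping %s chain %s: %s", path, chain_id, e)
            n_rejected += 1
            continue
        trace.source_id = chain_key
        pred = classify_trace(trace, method, subspace_model, eml_model,
                              do_postprocess=do_postprocess)
        tsv = write_predictions(trace, pred)
        if out_dir is not None:
            out = Path(out_dir) / f"{chain_key}.{method}.tsv"
            out.write_text(tsv)
        try:
            truth = read_sse_labels(text, trace)
        except ValueError:
            truth = None
        if truth is not None:
            per_chain[chain_key] = evaluate(pred, truth)
            pooled_pred.extend(pred)
            pooled_truth.extend(truth)
    if not per_chain and n_rejected:
        raise RuntimeError(f"all {n_rejected} chains were rejected")
    pooled = evaluate(LabelSequence(pooled_pred, provenance=method),
                      LabelSequence(pooled_truth)) if pooled_pred else None
    return per_chain, pooled


def report_to_json(report: EvalReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
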