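"""Classification reports, confusion matrices, discriminant-space plots,
and portable model serialization."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .dapc_core import DAModel, DAPCModel, PCModel
from .errors import ModelFormatError, ParameterError, ShapeError

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "confusion_matrix",
    "classification_report",
    "scatter_plot",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "dapcy-model-1"


@dataclass
class ConfusionMatrix:
    labels: list[str]
    matrix: np.ndarray  # rows = true, columns = predicted

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        k = len(self.labels)
        if self.matrix.shape != (k, k):
            raise ShapeError("confusion matrix must be k x k")
        if (self.matrix < 0).any():
            raise ParameterError("negative counts")

    @property
    def n_samples(self) -> int:
        return int(self.matrix.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.n_samples)

    def to_text(self) -> str:
        lines = ["true\\pred\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.matrix):
            lines.append(lab + "\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class ClassificationReport:
    # label -> {'recall', 'precision', 'support', 'precision_undefined'}
    per_class: dict[str, dict]
    overall_mean_accuracy: float  # sample-weighted, trace/n
    macro_mean_accuracy: float  # unweighted mean of per-class recall
    n_samples: int

    def to_text(self) -> str:
        lines = ["label\trecall\tprecision\tsupport"]
        for lab, row in self.per_class.items():
            prec = f"{row['precision']:.4f}"
            if row["precision_undefined"]:
                prec += "*"
            lines.append(f"{lab}\t{row['recall']:.4f}\t{prec}\t{row['support']}")
        lines.append(f"overall_mean_accuracy\t{self.overall_mean_accuracy:.4f}")
        lines.append(f"macro_mean_accuracy\t{self.macro_mean_accuracy:.4f}")
        lines.append("# * precision undefined (class never predicted)")
        return "\n".join(lines) + "\n"


def _label_vectors(true_labels, predicted_labels):
    t = np.asarray([str(x) for x in true_labels], dtype=object)
    p = np.asarray([str(x) for x in predicted_labels], dtype=object)
    if t.shape != p.shape:
        raise ShapeError("label vectors differ in length")
    if t.size == 0:
        raise ParameterError("empty label vectors")
    return t, p


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count matrix over the union of observed labels (rows = true)."""
    t, p = _label_vectors(true_labels, predicted_labels)
    labels = sorted(set(t) | set(p))
    index = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for ti, pi in zip(t, p):
        mat[index[ti], index[pi]] += 1
    return ConfusionMatrix(labels=labels, matrix=mat)


def classification_report(true_labels, predicted_labels) -> ClassificationReport:
    """Per-class recall/precision/support plus overall accuracies.

    Overall accuracy is sample-weighted (trace over n); the unweighted
    mean of per-class recalls is reported alongside. Precision for a
    never-predicted class is 0 and flagged undefined.
    """
    cm = confusion_matrix(true_labels, predicted_labels)
    per_class: dict[str, dict] = {}
    recalls = []
    for i, lab in enumerate(cm.labels):
        row_sum = int(cm.matrix[i].sum())
        col_sum = int(cm.matrix[:, i].sum())
        diag = int(cm.matrix[i, i])
        recall = diag / row_sum if row_sum else 0.0
        precision = diag / col_sum if col_sum else 0.0
        per_class[lab] = {
            "recall": recall,
            "precision": precision,
            "support": row_sum,
            "precision_undefined": col_sum == 0,
        }
        if row_sum:
            recalls.append(recall)
    return ClassificationReport(
        per_class=per_class,
        overall_mean_accuracy=cm.overall_accuracy,
        macro_mean_accuracy=float(np.mean(recalls)),
        n_samples=cm.n_samples,
    )


def scatter_plot(
    scores: np.ndarray,
    labels,
    outfile: str | os.PathLike,
    axes: tuple[int, int] = (0, 1),
    explained_variance: np.ndarray | None = None,
    title: str | None = None,
) -> str:
    """Scatter of samples in component space, coloured by label.

    With a single available component the plot falls back to a 1-D strip.
    Axis indices are 0-based. Output format follows the file extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "dapcy"  # deterministic SVG element ids

    X = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray([str(l) for l in labels], dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ShapeError("labels length does not match score rows")

    fig, ax = plt.subplots(figsize=(6, 5))
    classes = sorted(set(y))
    cmap = plt.get_cmap("tab10")
    one_d = X.shape[1] < 2
    if not one_d:
        i, j = axes
        if max(i, j) >= X.shape[1]:
            raise ShapeError(f"axes {axes} out of range for {X.shape[1]} components")
    for ci, lab in enumerate(classes):
        sel = y == lab
        color = cmap(ci % 10)
        if one_d:
            jitter = (np.arange(int(sel.sum())) % 7) / 10.0
            ax.scatter(X[sel, 0], jitter, s=14, color=color, label=lab)
        else:
            ax.scatter(X[sel, axes[0]], X[sel, axes[1]], s=14, color=color, label=lab)

    def _caption(idx: int) -> str:
        cap = f"component {idx + 1}"
        if explained_variance is not None and idx < len(explained_variance):
            cap += f" ({100 * explained_variance[idx]:.1f}%)"
        return cap

    if one_d:
        ax.set_xlabel(_caption(0))
        ax.set_yticks([])
    else:
        ax.set_xlabel(_caption(axes[0]))
        ax.set_ylabel(_caption(axes[1]))
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(outfile, metadata={"Date": None} if str(outfile).endswith(".svg") else None)
    plt.close(fig)
    return str(outfile)


def save_model(model: DAPCModel, path: str | os.PathLike) -> None:
    """Serialize a fitted model as a versioned archive of named arrays.

    Deliberately not a language-native object dump: the archive holds
    plain numeric arrays plus a JSON metadata document, so it can be
    reloaded across environments with round-trip fidelity.
    """
    pc, da = model.pc_model, model.da_model
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "centering_mode": pc.centering_mode,
        "class_labels": da.class_labels,
        "k": da.k,
        "r": pc.r,
        "provenance": model.provenance,
    }
    center = pc.center if pc.center is not None else np.zeros(0)
    np.savez(
        path,
        metadata=np.array(json.dumps(meta)),
        loadings=pc.loadings,
        singular_values=pc.singular_values,
        explained_variance_fraction=pc.explained_variance_fraction,
        center=center,
        discriminant_axes=da.discriminant_axes,
        class_means=da.class_means,
        class_priors=da.class_priors,
        pooled_within_scatter=da.pooled_within_scatter,
    )


def load_model(path: str | os.PathLike) -> DAPCModel:
    """Reload a model archive; version mismatches fail loudly."""
    try:
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["metadata"]))
            version = meta.get("format_version")
            if version != MODEL_FORMAT_VERSION:
                raise ModelFormatError(
                    f"model archive version {version!r} unsupported "
                    f"(expected {MODEL_FORMAT_VERSION!r})"
                )
            center = z["center"]
            pc = PCModel(
                r=int(meta["r"]),
                loadings=z["loadings"],
                singular_values=z["singular_values"],
                explained_variance_fraction=z["explained_variance_fraction"],
                center=center if center.size else None,
                centering_mode=meta["centering_mode"],
            )
            da = DAModel(
                k=int(meta["k"]),
                class_labels=list(meta["class_labels"]),
                discriminant_axes=z["discriminant_axes"],
                class_means=z["class_means"],
                class_priors=z["class_priors"],
                pooled_within_scatter=z["pooled_within_scatter"],
            )
            return DAPCModel(pc_model=pc, da_model=da, provenance=meta["provenance"])
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"cannot load model archive {path!r}: {exc}") from exc
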