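"""Write membership lists, per-cluster profile plots and the run report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from metaclust.kmeans_clustering import ClusterModel, KSelectionTrace  # noqa: E402

logger = logging.getLogger(__name__)


@dataclass
class ClusterReport:
    """Everything a run produces: the partition, the centers and run metadata.

    Member id lists over all clusters partition `ids` exactly: no feature is
    duplicated and none is missing.
    """

    ids: list[str]
    assignments: np.ndarray
    centers: np.ndarray
    k: int
    unclustered: np.ndarray  # positionwise mean over ALL rows
    trace: KSelectionTrace
    params: dict = field(default_factory=dict)
    skipped_features: int = 0

    @classmethod
    def from_model(
        cls,
        model: ClusterModel,
        ids: list[str],
        rows: np.ndarray,
        trace: KSelectionTrace,
        params: dict | None = None,
        skipped_features: int = 0,
    ) -> "ClusterReport":
        return cls(
            ids=list(ids),
            assignments=np.asarray(model.assignments),
            centers=np.asarray(model.centers),
            k=model.k,
            unclustered=np.asarray(rows).mean(axis=0),
            trace=trace,
            params=dict(params or {}),
            skipped_features=skipped_features,
        )

    def members(self, cluster: int) -> list[str]:
        return [name for name, a in zip(self.ids, self.assignments) if a == cluster]

    def member_counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)

    def validate_partition(self) -> None:
        all_members = [name for c in range(self.k) for name in self.members(c)]
        if sorted(all_members) != sorted(self.ids):
            raise ValueError("cluster membership lists do not partition the id set")


def write_membership(report: ClusterReport, out_dir: str | Path) -> list[Path]:
    """Write cluster_<i>.txt (one feature id per line, annotation order)
    and summary.tsv (feature_id, cluster_index)."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    report.validate_partition()
    written = []
    for c in range(report.k):
        path = out_dir / f"cluster_{c}.txt"
        path.write_text("".join(f"{name}\n" for name in report.members(c)))
        written.append(path)
    summary = out_dir / "summary.tsv"
    lines = ["feature_id\tcluster_index\n"]
    lines += [f"{name}\t{a}\n" for name, a in zip(report.ids, report.assignments)]
    summary.write_text("".join(lines))
    written.append(summary)
    return written


def _write_series_tsv(path: Path, values: np.ndarray) -> None:
    lines = ["position\tvalue\n"]
    lines += [f"{j}\t{v!r}\n" for j, v in enumerate(map(float, values))]
    path.write_text("".join(lines))


def _plot_series(path: Path, values: np.ndarray, title: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(values)), values)
    ax.set_xlabel("normalized position")
    ax.set_ylabel("mean signal")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_plots(
    report: ClusterReport, out_dir: str | Path, *, images: bool = True
) -> list[Path]:
    """One image per cluster center plus the unclustered mean profile.

    Each plotted y-series is also written as a .tsv so numeric content is
    testable without parsing images; `images=False` emits only the TSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = report.member_counts()
    written = []
    for c in range(report.k):
        if images:
            img = out_dir / f"cluster_{c}.png"
            _plot_series(img, report.centers[c], f"cluster {c} (n = {counts[c]})")
            written.append(img)
        _write_series_tsv(out_dir / f"plot_{c}.tsv", report.centers[c])
    if images:
        img = out_dir / "unclustered.png"
        _plot_series(img, report.unclustered, f"unclustered (n = {len(report.ids)})")
        written.append(img)
    _write_series_tsv(out_dir / "plot_unclustered.tsv", report.unclustered)
    return written


def write_run_report(report: ClusterReport, out_dir: str | Path) -> Path:
    """Serialize parameters, the D(k) trace and counts to run_report.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "selected_k": report.k,
        "n_features_clustered": len(report.ids),
        "n_features_skipped": report.skipped_features,
        "member_counts": [int(c) for c in report.member_counts()],
        "trace": [
            {"k": k, "total_distance": d, "relative_improvement": imp}
            for k, d, imp in report.trace.entries
        ],
        "params": report.params,
    }
    path = out_dir / "run_report.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
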