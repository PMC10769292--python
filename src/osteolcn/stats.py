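"""Batch orchestration and group comparison.

``run_batch`` segments every image in a directory and extracts one
connectomics report per image.  ``compare_groups`` compares two groups of
reports metric-by-metric with a two-sided two-sample Student's t-test
(pooled variance; Welch's available behind a flag) at a configurable alpha
(default 1e-4), reporting mean +/- SD per group.  The statistical unit is the
per-image report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectomics import ConnectomicsReport, extract_graph
from .threshold import ThresholdConfig, segment
from . import io as lcn_io

__all__ = ["GroupComparison", "run_batch", "compare_groups", "reports_to_frame"]

logger = logging.getLogger(__name__)

#: metrics compared between groups, in report order
METRIC_COLUMNS = [
    "n_nodes",
    "dead_ends_per_node",
    "connections_per_node",
    "mean_connection_length_um",
    "mean_connection_diameter_um",
    "mean_network_diameter_um",
    "mean_shortest_path",
    "mean_dendrite_length_um",
]


@dataclass
class GroupComparison:
    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    alpha: float
    significant: bool

    def as_dict(self) -> dict:
        return dataclasses_asdict(self)


def dataclasses_asdict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def reports_to_frame(reports: list[ConnectomicsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


def run_batch(
    input_dir: str | Path,
    method: str = "otsu",
    cfg: ThresholdConfig = ThresholdConfig(),
    um_per_px: float = 0.284,
    predictor=None,
) -> pd.DataFrame:
    """Segment and measure every image in a directory.

    ``method`` is ``"otsu"``, ``"canny"`` or ``"model"``; the last requires a
    ``predictor`` callable mapping a grayscale image to a label mask.
    Unreadable or failing files are logged and skipped; rows are ordered by
    filename.  Returns one row of connectomics metrics per image plus an
    ``image`` column (and the failure count in ``DataFrame.attrs['n_failed']``).
    """
    input_dir = Path(input_dir)
    paths = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png") and not p.stem.endswith("_mask")
    )
    if not paths:
        logger.warning("no images found in %s", input_dir)
    rows = []
    n_failed = 0
    for path in paths:
        try:
            image = lcn_io.read_image(path)
            if method == "model":
                if predictor is None:
                    raise ValueError("method='model' requires a predictor")
                label = predictor(image)
            else:
                label = segment(image, method=method, cfg=cfg)
            _, report = extract_graph(label, um_per_px=um_per_px)
            row = {"image": path.name}
            row.update(report.as_dict())
            rows.append(row)
        except Exception:
            n_failed += 1
            logger.exception("failed to process %s; skipping", path)
    frame = pd.DataFrame(rows)
    frame.attrs["n_failed"] = n_failed
    return frame


def _student_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf") * np.sign(np.mean(a) - np.mean(b)), 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    reports_a: pd.DataFrame | list[ConnectomicsReport],
    reports_b: pd.DataFrame | list[ConnectomicsReport],
    alpha: float = 1e-4,
    welch: bool = False,
    metrics: list[str] = METRIC_COLUMNS,
) -> list[GroupComparison]:
    """Two-sided t-test per metric between two groups of per-image reports.

    NaN metric values (e.g. mean connection length of an image with no
    recovered connections) are dropped per metric.  Each group needs at least
    two finite values per metric; metrics without that support are skipped.
    """
    if not isinstance(reports_a, pd.DataFrame):
        reports_a = reports_to_frame(reports_a)
    if not isinstance(reports_b, pd.DataFrame):
        reports_b = reports_to_frame(reports_b)

    out: list[GroupComparison] = []
    for metric in metrics:
        if metric not in reports_a.columns or metric not in reports_b.columns:
            continue
        a = np.asarray(reports_a[metric], dtype=np.float64)
        b = np.asarray(reports_b[metric], dtype=np.float64)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            logger.warning("metric %s: fewer than 2 finite values per group; skipped", metric)
            continue
        t, p = _student_t(a, b, welch)
        out.append(
            GroupComparison(
                metric=metric,
                mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)), n_a=len(a),
                mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)), n_b=len(b),
                t_statistic=t, p_value=p, alpha=alpha, significant=bool(p < alpha),
            )
        )
    return out
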