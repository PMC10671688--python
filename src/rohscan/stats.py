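"""Length-class descriptive statistics and F_ROH inbreeding coefficients.

F_ROH for one individual at a length threshold e (Mb) is

    F_ROH(>e) = sum(L_ROH, over segments longer than e Mb) / L_aut

where L_aut is the autosomal length covered by SNPs on the array
(per-chromosome span between the first and last mapped SNP, summed).
Because every threshold is computed from one segment set, F_ROH is
non-increasing in e by construction.

Length classes come in two views over the same edges (default
1, 2, 4, 8, 16 Mb): cumulative classes "e+" (segment length >= e) and
interval classes "[e_i, e_{i+1})" with a final open ">last" class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import ROHSegment
from .model import SampleRecord, SNPRecord


@dataclass(frozen=True)
class LengthClassScheme:
    edges_mb: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)

    def __post_init__(self) -> None:
        e = self.edges_mb
        if not e or any(x <= 0 for x in e) or any(
            b <= a for a, b in zip(e, e[1:])
        ):
            raise ValueError("edges_mb must be strictly increasing and positive")

    @property
    def cumulative_labels(self) -> list[str]:
        return [f"{_fmt(e)}+" for e in self.edges_mb]

    @property
    def interval_labels(self) -> list[str]:
        e = self.edges_mb
        labels = [f"{_fmt(a)}-{_fmt(b)}" for a, b in zip(e, e[1:])]
        labels.append(f">{_fmt(e[-1])}")
        return labels


def _fmt(x: float) -> str:
    return f"{x:g}"


def autosomal_span(snps: Sequence[SNPRecord]) -> int:
    """L_aut: summed per-chromosome span (max - min position + 1) in bp."""
    if not snps:
        raise ValueError("empty SNP map: L_aut undefined")
    spans: dict[int, tuple[int, int]] = {}
    for s in snps:
        lo, hi = spans.get(s.chromosome, (s.position_bp, s.position_bp))
        spans[s.chromosome] = (min(lo, s.position_bp), max(hi, s.position_bp))
    return sum(hi - lo + 1 for lo, hi in spans.values())


def classify_segments(
    segments: Sequence[ROHSegment], scheme: LengthClassScheme | None = None
) -> tuple[dict[str, list[ROHSegment]], dict[str, list[ROHSegment]]]:
    """Bin segments by length: (interval view, cumulative view).

    Interval classes partition the segments (left-closed, right-open in
    Mb; a segment of exactly 2.0 Mb falls in [2, 4)); the cumulative
    class "e+" holds every segment of length >= e.  A segment shorter
    than the smallest edge is an error: detection should not emit one
    when ``min_length_kb`` matches the scheme.
    """
    scheme = scheme or LengthClassScheme()
    edges = scheme.edges_mb
    intervals: dict[str, list[ROHSegment]] = {l: [] for l in scheme.interval_labels}
    cumulative: dict[str, list[ROHSegment]] = {l: [] for l in scheme.cumulative_labels}
    for seg in segments:
        mb = seg.length_bp / 1e6
        if mb < edges[0]:
            raise ValueError(
                f"segment of {mb:.3f} Mb below smallest class edge {edges[0]} Mb"
            )
        k = int(np.searchsorted(edges, mb, side="right")) - 1
        intervals[scheme.interval_labels[k]].append(seg)
        for e, label in zip(edges, scheme.cumulative_labels):
            if mb >= e:
                cumulative[label].append(seg)
    return intervals, cumulative


def _per_individual_frame(
    segments: Sequence[ROHSegment],
    samples: Sequence[SampleRecord],
    scheme: LengthClassScheme,
) -> pd.DataFrame:
    """Count and total length (Mb) per individual per cumulative class.

    Individuals with zero segments appear with zeros.
    """
    rows = {s.individual_id: s for s in samples}
    if len(rows) != len(samples):
        raise ValueError("individual_id not unique across roster")
    data = {
        iid: {f"n_{l}": 0 for l in scheme.cumulative_labels}
        | {f"mb_{l}": 0.0 for l in scheme.cumulative_labels}
        for iid in rows
    }
    for seg in segments:
        if seg.individual_id not in data:
            raise ValueError(f"segment individual {seg.individual_id!r} not in roster")
        mb = seg.length_bp / 1e6
        for e, label in zip(scheme.edges_mb, scheme.cumulative_labels):
            if mb >= e:
                data[seg.individual_id][f"n_{label}"] += 1
                data[seg.individual_id][f"mb_{label}"] += mb
    frame = pd.DataFrame.from_dict(data, orient="index")
    frame.index.name = "individual_id"
    frame["population"] = [rows[i].population_label for i in frame.index]
    return frame


def summarize_population(
    segments: Sequence[ROHSegment],
    samples: Sequence[SampleRecord],
    scheme: LengthClassScheme | None = None,
) -> pd.DataFrame:
    """Per-population mean/SD/min/max of ROH count and total length (Mb).

    One row per (population, metric, class); SD is the sample standard
    deviation (n-1), reported as 0 for single-individual populations.
    Zero-segment individuals contribute zeros.
    """
    scheme = scheme or LengthClassScheme()
    if not samples:
        raise ValueError("no individuals given")
    frame = _per_individual_frame(segments, samples, scheme)
    records = []
    for pop, grp in frame.groupby("population", sort=True):
        for metric, prefix in (("n_roh", "n_"), ("length_mb", "mb_")):
            for label in scheme.cumulative_labels:
                col = grp[f"{prefix}{label}"]
                sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
                records.append(
                    {
                        "population": pop,
                        "metric": metric,
                        "class_mb": label,
                        "mean": float(col.mean()),
                        "sd": sd,
                        "min": float(col.min()),
                        "max": float(col.max()),
                        "n_individuals": int(len(col)),
                    }
                )
    return pd.DataFrame.from_records(records)


def compute_froh(
    segments: Sequence[ROHSegment],
    l_aut: int,
    edges_mb: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0),
) -> dict[float, float]:
    """F_ROH of one individual at each threshold (strictly-longer rule)."""
    if l_aut <= 0:
        raise ValueError("l_aut must be positive")
    for seg in segments:
        if seg.length_bp > l_aut:
            raise ValueError(
                f"segment of {seg.length_bp} bp exceeds L_aut={l_aut} bp"
            )
    out: dict[float, float] = {}
    for e in edges_mb:
        total = sum(s.length_bp for s in segments if s.length_bp > e * 1e6)
        out[float(e)] = total / l_aut
    return out


def froh_table(
    segments: Sequence[ROHSegment],
    samples: Sequence[SampleRecord],
    l_aut: int,
    scheme: LengthClassScheme | None = None,
) -> pd.DataFrame:
    """Per-individual F_ROH at every threshold, plus the population label.

    Columns ``froh_gt_<e>mb``; use ``groupby('population').mean()`` for
    the population view.
    """
    scheme = scheme or LengthClassScheme()
    by_iid: dict[str, list[ROHSegment]] = {s.individual_id: [] for s in samples}
    for seg in segments:
        if seg.individual_id not in by_iid:
            raise ValueError(f"segment individual {seg.individual_id!r} not in roster")
        by_iid[seg.individual_id].append(seg)
    rows = []
    for s in samples:
        froh = compute_froh(by_iid[s.individual_id], l_aut, scheme.edges_mb)
        rows.append(
            {"individual_id": s.individual_id, "population": s.population_label}
            | {f"froh_gt_{_fmt(e)}mb": froh[e] for e in scheme.edges_mb}
        )
    return pd.DataFrame.from_records(rows).set_index("individual_id")


def population_froh_means(table: pd.DataFrame) -> pd.DataFrame:
    """Population-mean F_ROH per threshold from :func:`froh_table` output."""
    return table.groupby("population").mean(numeric_only=True)


__all__ = [
    "LengthClassScheme",
    "autosomal_span",
    "classify_segments",
    "summarize_population",
    "compute_froh",
    "froh_table",
    "population_froh_means",
]
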