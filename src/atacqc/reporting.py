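"""Report serialization: combined JSON, per-sample text, multi-report merge.

The JSON document is the authoritative superset — every number printed in
the text rendering is derivable from it.  The schema is versioned; readers
tolerate unknown fields, the writer is strict (a structural validator runs
on every document written).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .metrics import QCReport

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "report_to_dict",
    "to_json",
    "read_json",
    "to_text",
    "merge_reports",
]

SCHEMA_VERSION = "1.0"

# (field name, type or tuple of types, nullable)
_SAMPLE_FIELDS = [
    ("tool", str, False),
    ("version", str, False),
    ("timestamp", str, False),
    ("input_path", str, False),
    ("parameters", dict, False),
    ("catalog", dict, False),
    ("category_counts", dict, False),
    ("category_percent_total", dict, False),
    ("type_percent_mapped", dict, False),
    ("passing_total", int, False),
    ("stats", dict, False),
    ("histograms", dict, False),
    ("effective_genome", int, False),
    ("bases_covered", int, False),
    ("coverage_fraction", (int, float), True),
    ("mean_depth", (int, float), True),
    ("reads_streamed", int, False),
    ("frip", (int, float), True),
    ("tes", (int, float), True),
    ("tss_pileup", dict, True),
    ("peak_pileup", dict, True),
    ("footprint", dict, True),
    ("periodicity", (int, float), True),
    ("grid", list, True),
    ("single_end", bool, False),
]


class SchemaError(ValueError):
    """A JSON document that does not match the report schema."""


def _validate_sample(sample: dict, where: str = "") -> None:
    prefix = f"{where}: " if where else ""
    if not isinstance(sample, dict):
        raise SchemaError(f"{prefix}sample report is not an object")
    for name, types, nullable in _SAMPLE_FIELDS:
        if name not in sample:
            raise SchemaError(f"{prefix}missing field {name!r}")
        value = sample[name]
        if value is None:
            if not nullable:
                raise SchemaError(f"{prefix}field {name!r} must not be null")
            continue
        if not isinstance(value, types):
            raise SchemaError(
                f"{prefix}field {name!r} has type {type(value).__name__}"
            )


def validate_document(doc: dict, where: str = "") -> None:
    prefix = f"{where}: " if where else ""
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise SchemaError(f"{prefix}missing schema_version")
    if "samples" not in doc or not isinstance(doc["samples"], list) or not doc["samples"]:
        raise SchemaError(f"{prefix}document must carry a non-empty samples array")
    for i, s in enumerate(doc["samples"]):
        _validate_sample(s, where=f"{where or 'document'} sample {i}")


def report_to_dict(report: QCReport) -> dict:
    d = dataclasses.asdict(report)
    # numbers at full precision; numpy scalars/arrays to plain Python
    return json.loads(json.dumps(d, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)!r}")


def to_json(reports: Sequence[QCReport], path: Union[str, Path]) -> dict:
    """Write one combined JSON document for >= 1 reports and return it."""
    if not reports:
        raise ValueError("to_json requires at least one report")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "samples": [report_to_dict(r) for r in reports],
    }
    validate_document(doc)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return doc


def read_json(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    validate_document(doc, where=str(path))
    return doc


def _fmt(value: Optional[float], pct: bool = False, digits: int = 2) -> str:
    if value is None:
        return "n/a"
    return f"{value:.{digits}f}" + ("%" if pct else "")


def to_text(report: QCReport) -> str:
    """Fixed-layout human-readable per-sample summary."""
    r = report
    lines: list[str] = []
    add = lines.append
    add(f"{r.tool} v{r.version} — QC report")
    add(f"input:     {r.input_path}")
    add(f"generated: {r.timestamp}")
    p = r.parameters
    maxf = p.get("max_fragment")
    add(
        "filters:   mode={mode} use_all={ua} min_mapq={mq} fragment=[{lo}, {hi}] "
        "nuclear_only={nuc}".format(
            mode=p.get("mode"), ua=p.get("use_all"), mq=p.get("min_mapq"),
            lo=p.get("min_fragment"), hi="inf" if maxf is None else maxf,
            nuc=p.get("nuclear_only"),
        )
    )
    add(
        "signal:    tn5_shift={t} resize={rs} pileup_anchor={pa}".format(
            t=p.get("tn5_shift"), rs=p.get("resize"), pa=p.get("pileup_anchor"),
        )
    )
    cat = r.catalog
    add(
        "reference: {n} sequences ({c[nuclear]} nuclear, {c[mitochondrial]} "
        "mitochondrial, {c[plastid]} plastid); nuclear size {sz} bp".format(
            n=cat["n_sequences"], c=cat["counts"], sz=cat["nuclear_size"]
        )
    )
    add("")
    add("Read categories (percent of total reads)")
    add(f"  {'category':<15}{'total':>10}{'mapped':>10}{'% total':>10}")
    total = 0
    for c in ("nuclear", "mitochondrial", "plastid"):
        cc = r.category_counts[c]
        total += cc["total"]
        add(
            f"  {c:<15}{cc['total']:>10}{cc['mapped']:>10}"
            f"{_fmt(r.category_percent_total[c]):>10}"
        )
    add(f"  {'all':<15}{total:>10}")
    add("")
    add("Read types (percent of mapped reads)")
    type_counts = {
        k: sum(r.category_counts[c][k] for c in ("nuclear", "mitochondrial", "plastid"))
        for k in ("duplicate", "secondary", "supplementary", "qc_fail", "proper_pair", "passing")
    }
    for k in type_counts:
        add(
            f"  {k:<15}{type_counts[k]:>10}"
            f"{_fmt(r.type_percent_mapped[k]):>10}"
        )
    add("")
    add(f"Passing reads: {r.passing_total}")
    if r.single_end:
        add("Fragment statistics unavailable (single-end data)")
    else:
        s = r.stats["fragment_length"]
        add(
            "Fragment length: mean={m} sd={sd} median={md} min={mn} max={mx}".format(
                m=_fmt(s["mean"]), sd=_fmt(s["sd"]), md=_fmt(s["median"]),
                mn=_fmt(s["min"], digits=0), mx=_fmt(s["max"], digits=0),
            )
        )
    for label, key in (
        ("Alignment length", "alignment_length"),
        ("MAPQ", "mapq"),
        ("GC percent", "gc_percent"),
        ("Depth", "depth"),
    ):
        s = r.stats[key]
        add(
            f"{label}: mean={_fmt(s['mean'])} sd={_fmt(s['sd'])} "
            f"median={_fmt(s['median'])} min={_fmt(s['min'], digits=0)} "
            f"max={_fmt(s['max'], digits=0)}"
        )
    add(
        f"Genome coverage: {_fmt(None if r.coverage_fraction is None else 100 * r.coverage_fraction, pct=True)}"
        f" of {r.effective_genome} bp effective genome; mean depth {_fmt(r.mean_depth)}"
    )
    add("")
    if r.frip is None:
        add("FRiP: n/a (no peaks file provided or no passing reads)")
    else:
        add(f"FRiP: {r.frip:.4f}")
    if r.tes is None:
        add("TSS enrichment: n/a (no TSS file provided)")
    else:
        add(f"TSS enrichment: {r.tes:.4f}")
    if r.periodicity is None:
        add("Fragment-length periodicity: n/a")
    else:
        add(f"Fragment-length periodicity: {r.periodicity:.2f} bp")
    if r.footprint is not None:
        add(f"Footprint profile: {r.footprint['n_anchors']} sites, radius {r.footprint['radius']} bp")
    if r.grid:
        add("")
        add("Parameter grid search")
        add(f"  {'min_mapq':>9}{'min_flen':>9}{'max_flen':>9}{'passing':>10}{'TES':>9}")
        for row in r.grid:
            tes = "n/a" if row["tes"] is None else f"{row['tes']:.3f}"
            add(
                f"  {row['min_mapq']:>9}{row['min_fragment']:>9}"
                f"{row['max_fragment']:>9}{row['passing']:>10}{tes:>9}"
            )
    add("")
    return "\n".join(lines)


_SCALAR_METRICS = (
    "reads_streamed",
    "passing_total",
    "effective_genome",
    "bases_covered",
    "coverage_fraction",
    "mean_depth",
    "frip",
    "tes",
    "periodicity",
)


def merge_reports(paths: Sequence[Union[str, Path]]) -> dict:
    """Merge JSON report files into a side-by-side comparison structure.

    Returns ``{"scalars": long DataFrame keyed by (sample, metric),
    "histograms": {name: wide DataFrame, samples x bins padded to common
    support}, "pileups": likewise}``.  Any schema version this package has
    ever written is accepted; a mismatched file raises SchemaError naming
    it.
    """
    samples: list[tuple[str, dict]] = []
    for path in paths:
        doc = read_json(path)  # raises SchemaError with the file name
        for s in doc["samples"]:
            key = s["input_path"] or str(path)
            base = key
            k = 1
            existing = {name for name, _ in samples}
            while key in existing:
                k += 1
                key = f"{base}#{k}"
            samples.append((key, s))

    rows = []
    for name, s in samples:
        for metric in _SCALAR_METRICS:
            rows.append({"sample": name, "metric": metric, "value": s[metric]})
        for c in ("nuclear", "mitochondrial", "plastid"):
            for k, v in s["category_counts"][c].items():
                rows.append({"sample": name, "metric": f"{c}.{k}", "value": v})
    scalars = pd.DataFrame(rows)

    histograms: dict[str, pd.DataFrame] = {}
    for hist_name in ("fragment_length", "alignment_length", "mapq", "gc_percent"):
        data = {name: np.asarray(s["histograms"][hist_name]) for name, s in samples}
        width = max(len(v) for v in data.values())
        histograms[hist_name] = pd.DataFrame(
            {name: np.pad(v, (0, width - len(v))) for name, v in data.items()}
        ).T

    pileups: dict[str, pd.DataFrame] = {}
    for key in ("tss_pileup", "peak_pileup", "footprint"):
        have = {name: s[key] for name, s in samples if s[key] is not None}
        if not have:
            continue
        width = max(len(p["values"]) for p in have.values())
        pileups[key] = pd.DataFrame(
            {
                name: np.pad(np.asarray(p["values"]), (0, width - len(p["values"])))
                for name, p in have.items()
            }
        ).T
    return {"scalars": scalars, "histograms": histograms, "pileups": pileups}
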