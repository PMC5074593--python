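"""Tabular reports and the run manifest.

Reports mirror the layout of published path tables: one row per
(state, pathway class) with N, integer-rounded W, min correlation and the
effectiveness flag.  Machine-readable output keeps full precision; only
the human-readable table rounds.  Output is byte-deterministic for a
fixed configuration and seed, which the manifest records together with
input digests and every threshold in effect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path as FilePath
from typing import Sequence

import pandas as pd

from .paths import EFFECTIVE_MIN_CORR, Path, classify_effective


@dataclass
class PathReportRow:
    state: str
    pair: str  # e.g. "A:36-A:620"
    path_class: str
    n_hops: int
    weight100: float
    min_corr: float
    effective: bool
    node_labels: list[str] = field(default_factory=list)


def make_report_row(
    path: Path,
    state: str,
    pair: str,
    path_class: str = "",
    labels: Sequence[str] | None = None,
    threshold: float = EFFECTIVE_MIN_CORR,
) -> PathReportRow:
    rep = classify_effective(path, threshold)
    return PathReportRow(
        state=state,
        pair=pair,
        path_class=path_class,
        n_hops=path.n_hops,
        weight100=path.weight100,
        min_corr=path.min_corr,
        effective=rep.effective,
        node_labels=list(labels) if labels is not None else [str(n) for n in path.nodes],
    )


def render_path_table(rows: Sequence[PathReportRow]) -> pd.DataFrame:
    """Human-readable table: W rounded to integer, min to 2 decimals."""
    return pd.DataFrame(
        [
            {
                "state": r.state,
                "pair": r.pair,
                "path_class": r.path_class,
                "N": r.n_hops,
                "W": int(round(r.weight100)),
                "min": round(r.min_corr, 2),
                "effective": r.effective,
                "path": "-".join(r.node_labels),
            }
            for r in rows
        ]
    )


def write_reports(
    rows: Sequence[PathReportRow],
    outdir: str | FilePath,
    manifest: dict | None = None,
    basename: str = "paths",
) -> dict[str, FilePath]:
    """Write the table as TSV (rounded) and JSON (full precision), plus a
    manifest; output is byte-identical across reruns of the same inputs."""
    outdir = FilePath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / f"{basename}.tsv"
    render_path_table(rows).to_csv(tsv, sep="\t", index=False)
    js = outdir / f"{basename}.json"
    js.write_text(
        json.dumps([asdict(r) for r in rows], indent=2, sort_keys=True) + "\n"
    )
    out = {"tsv": tsv, "json": js}
    if manifest is not None:
        mf = outdir / "manifest.json"
        mf.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        out["manifest"] = mf
    return out


def file_digest(path: str | FilePath) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    settings: dict,
    seeds: dict | None = None,
    inputs: Sequence[str | FilePath] = (),
) -> dict:
    """Run manifest: every design-decision setting, seeds, input digests."""
    return {
        "settings": settings,
        "seeds": seeds or {},
        "inputs": {str(p): file_digest(p) for p in inputs},
    }
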