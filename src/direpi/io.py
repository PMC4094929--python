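"""Readers and writers for the package's table and report formats.

Tables are plain CSV/TSV (delimiter inferred from the extension, ``.tsv``
meaning tab); reports are JSON or TSV.  Genotype-phenotype tables have
columns ``id, phenotype, <locus>...`` with dosages in [0, 2] ("NA" marks a
missing genotype); selection series have columns
``generation, mean, line`` with line labels "up"/"down"; mutation-count
tables have columns ``m, phenotype``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import f_scale
from .linecross import CrossEstimates
from .mutcount import MutationCountData, PowerFit, QuadFit
from .qtl import GenoPhenoTable, QtlFit
from .selection import ResponseEstimates, SelectionSeries

__all__ = [
    "read_genopheno",
    "write_genopheno",
    "read_selection_series",
    "write_selection_series",
    "read_mutcount",
    "write_mutcount",
    "write_report",
    "linecross_report",
    "selresp_report",
    "qtl_report",
    "mutcount_report",
]


def _delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_genopheno(path: str | Path, delimiter: str | None = None) -> GenoPhenoTable:
    """Read a genotype-phenotype table (columns id, phenotype, loci...)."""
    df = pd.read_csv(path, sep=_delimiter(path, delimiter),
                     na_values=["NA"], skipinitialspace=True)
    required = {"id", "phenotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns "
                         f"{sorted(required - set(df.columns))}")
    locus_cols = [c for c in df.columns if c not in ("id", "phenotype")]
    if not locus_cols:
        raise ValueError(f"{path}: no locus columns found")
    if df["phenotype"].isna().any():
        rows = (df.index[df["phenotype"].isna()] + 2).tolist()
        raise ValueError(f"{path}: missing phenotype at line(s) {rows}")
    geno = df[locus_cols].to_numpy(dtype=float)
    bad = (geno < 0) | (geno > 2)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: dosage {geno[r, c]} out of [0, 2] at line {r + 2}, "
            f"column {locus_cols[c]}"
        )
    return GenoPhenoTable(
        phenotype=df["phenotype"].to_numpy(dtype=float),
        genotypes=geno,
        locus_labels=locus_cols,
    )


def write_genopheno(table: GenoPhenoTable, path: str | Path,
                    delimiter: str | None = None) -> None:
    df = pd.DataFrame(table.genotypes, columns=table.locus_labels)
    df.insert(0, "phenotype", table.phenotype)
    df.insert(0, "id", np.arange(1, table.n_individuals + 1))
    df.to_csv(path, sep=_delimiter(path, delimiter), index=False, na_rep="NA")


def read_selection_series(
    path: str | Path, delimiter: str | None = None, require_both: bool = True
) -> tuple[SelectionSeries | None, SelectionSeries | None]:
    """Read up/down selection trajectories (columns generation, mean, line)."""
    df = pd.read_csv(path, sep=_delimiter(path, delimiter),
                     skipinitialspace=True)
    missing = {"generation", "mean", "line"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    labels = set(df["line"].unique())
    if not labels.issubset({"up", "down"}):
        raise ValueError(f"{path}: unknown line labels {sorted(labels - {'up', 'down'})}")
    if require_both and labels != {"up", "down"}:
        raise ValueError(
            f"{path}: both 'up' and 'down' lines are required for the "
            f"asymmetry estimator (found {sorted(labels)})"
        )
    out: dict[str, SelectionSeries | None] = {"up": None, "down": None}
    for label, sub in df.groupby("line"):
        out[label] = SelectionSeries(
            sub["generation"].to_numpy(dtype=float),
            sub["mean"].to_numpy(dtype=float),
            line_label=label,
        )
    return out["up"], out["down"]


def write_selection_series(
    series: list[SelectionSeries], path: str | Path,
    delimiter: str | None = None,
) -> None:
    frames = [
        pd.DataFrame({"generation": s.generation, "mean": s.mean_phenotype,
                      "line": s.line_label})
        for s in series
    ]
    pd.concat(frames).to_csv(path, sep=_delimiter(path, delimiter), index=False)


def read_mutcount(path: str | Path, delimiter: str | None = None) -> MutationCountData:
    df = pd.read_csv(path, sep=_delimiter(path, delimiter),
                     skipinitialspace=True)
    missing = {"m", "phenotype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return MutationCountData(df["m"].to_numpy(dtype=float),
                             df["phenotype"].to_numpy(dtype=float))


def write_mutcount(data: MutationCountData, path: str | Path,
                   delimiter: str | None = None) -> None:
    pd.DataFrame({"m": data.m, "phenotype": data.phenotype}).to_csv(
        path, sep=_delimiter(path, delimiter), index=False
    )


# -- reports ---------------------------------------------------------------


def _rounded(d: dict, sig: int = 4) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = _rounded(v, sig)
        elif isinstance(v, float) and np.isfinite(v) and v != 0:
            out[k] = float(f"{v:.{sig}g}")
        else:
            out[k] = v
    return out


def linecross_report(est: CrossEstimates, fscale_delta: float = 100.0) -> dict:
    return {
        "model": "line_cross",
        "mu": est.mu,
        "A": est.A,
        "D": est.D,
        "eps": est.eps,
        "rss": est.rss,
        "f100": f_scale(est.eps, fscale_delta),
    }


def selresp_report(est: ResponseEstimates, fscale_delta: float = 100.0) -> dict:
    d = est.to_dict()
    d["model"] = "selection_response"
    d["f100"] = f_scale(est.epsilon, fscale_delta)
    return d


def qtl_report(fit: QtlFit, fscale_delta: float = 100.0) -> dict:
    d = fit.to_dict()
    if fit.eps is not None:
        d["f100"] = f_scale(fit.eps, fscale_delta)
    return d


def mutcount_report(fit: PowerFit | QuadFit) -> dict:
    d = fit.to_dict()
    d["model"] = "power" if isinstance(fit, PowerFit) else "quadratic"
    return d


def write_report(report: dict, path: str | Path, format: str = "json") -> None:
    """Serialize a fit report.

    JSON reports carry full-precision values plus a ``rounded`` block for
    human readers; TSV reports have one ``name<TAB>value`` row per scalar
    parameter (nested keys joined with '.').
    """
    path = Path(path)
    if format == "json":
        payload = dict(report)
        payload["rounded"] = _rounded(report)
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "tsv":
        rows: list[tuple[str, object]] = []

        def walk(prefix: str, obj: object) -> None:
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(f"{prefix}[{i}]", v)
            else:
                rows.append((prefix, obj))

        walk("", report)
        with path.open("w") as fh:
            fh.write("parameter\tvalue\n")
            for name, value in rows:
                fh.write(f"{name}\t{value}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
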