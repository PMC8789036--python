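"""Replicate PSI matrices, ΔPSI tables, rankings and library summaries.

The screen measures percent spliced-in (PSI, 0–100%) for every library
pentamer in replicate transfections, alongside a wild-type control minigene
per replicate batch.  The analysis metric is ΔPSI = mutant PSI − matched
wild-type PSI, averaged over replicates; pentamers are ranked by ΔPSI
(descending) for preranked enrichment.

The data matrix follows the GCT v1.2 layout used by enrichment tools: four
rows (MUT_PSI_R1, WT_PSI_R1, MUT_PSI_R2, WT_PSI_R2) by 1024 pentamer
columns.  WT rows broadcast a single per-batch control measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import LibraryContext, enumerate_library, normalize_rna, validate_pentamer

PSI_ROWS = ("MUT_PSI_R1", "WT_PSI_R1", "MUT_PSI_R2", "WT_PSI_R2")

#: ΔPSI values are reported to two decimals; zero-ΔPSI detection happens at
#: that precision.
REPORT_DECIMALS = 2


class GctParseError(ValueError):
    """Raised for malformed or invalid GCT input."""


def _mut_wt_rows(index) -> list[tuple[str, str]]:
    """Pair MUT/WT row names per replicate, in replicate order."""
    pairs = []
    for name in index:
        if name.startswith("MUT_PSI_"):
            rep = name.removeprefix("MUT_PSI_")
            wt = f"WT_PSI_{rep}"
            if wt not in index:
                raise GctParseError(f"row {name} has no matching {wt} row")
            pairs.append((name, wt))
    if not pairs:
        raise GctParseError("no MUT_PSI_* rows found")
    return pairs


def validate_psi_matrix(df: pd.DataFrame,
                        ctx: LibraryContext | None = None) -> pd.DataFrame:
    """Validate a PSI matrix: row names, the full 1024-pentamer column set,
    value range [0, 100] and per-replicate constant WT rows."""
    ctx = ctx or LibraryContext()
    cols = [validate_pentamer(c) for c in df.columns]
    df = df.copy()
    df.columns = cols
    library = enumerate_library(ctx)
    missing = sorted(set(library) - set(cols))
    if missing:
        raise GctParseError(
            f"matrix is missing {len(missing)} library pentamer(s), "
            f"first missing: {missing[0]}")
    extra = sorted(set(cols) - set(library))
    if extra:
        raise GctParseError(f"unknown pentamer column(s): {extra[:5]}")
    if len(cols) != len(set(cols)):
        dup = pd.Index(cols)[pd.Index(cols).duplicated()].tolist()
        raise GctParseError(f"duplicate pentamer column(s): {dup[:5]}")
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise GctParseError("PSI matrix contains non-finite values")
    if vals.min() < 0 or vals.max() > 100:
        bad = df.columns[np.where((vals < 0) | (vals > 100))[1][0]]
        raise GctParseError(
            f"PSI values must lie in [0, 100]; offending column: {bad}")
    _mut_wt_rows(df.index)
    for name in df.index:
        if name.startswith("WT_PSI_"):
            row = df.loc[name].to_numpy(dtype=float)
            if not np.allclose(row, row[0]):
                raise GctParseError(
                    f"WT row {name} is not constant (per-batch control broadcast)")
    return df[library]


def read_gct(path, ctx: LibraryContext | None = None) -> pd.DataFrame:
    """Read and validate a PSI matrix from a GCT v1.2 file."""
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "#1.2":
            raise GctParseError(f"expected GCT header '#1.2', got {header!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise GctParseError("malformed GCT dimension line")
        nrow, ncol = (int(x) for x in dims)
        body = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" not in body.columns:
        raise GctParseError("GCT body lacks a Description column")
    data = body.drop(columns=["Description"])
    if data.shape != (nrow, ncol):
        raise GctParseError(
            f"GCT dimension line says {nrow}x{ncol} but body is "
            f"{data.shape[0]}x{data.shape[1]}")
    data.columns = [normalize_rna(c) for c in data.columns]
    data = data.astype(float)
    data.index.name = None
    return validate_psi_matrix(data, ctx)


def write_gct(df: pd.DataFrame, path, descriptions: dict | None = None) -> None:
    """Write a PSI matrix in GCT v1.2 format (header line '#1.2')."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(df.columns) + "\n")
        for name, row in df.iterrows():
            desc = descriptions.get(name, "na")
            vals = "\t".join(f"{v:.6g}" for v in row.to_numpy(dtype=float))
            fh.write(f"{name}\t{desc}\t{vals}\n")


def compute_delta_psi(matrix: pd.DataFrame,
                      ctx: LibraryContext | None = None) -> pd.DataFrame:
    """Per-pentamer ΔPSI: mean over replicates of (MUT − matched WT).

    Returns a DataFrame indexed by pentamer with one ``delta_<rep>`` column
    per replicate and the averaged ``delta_psi``.  The wild-type pentamer is
    its own control and is fixed at 0.
    """
    ctx = ctx or LibraryContext()
    matrix = validate_psi_matrix(matrix, ctx)
    pairs = _mut_wt_rows(matrix.index)
    out = pd.DataFrame(index=matrix.columns)
    for mut, wt in pairs:
        rep = mut.removeprefix("MUT_PSI_")
        out[f"delta_{rep}"] = matrix.loc[mut] - matrix.loc[wt]
    out["delta_psi"] = out.mean(axis=1)
    out.loc[ctx.wt_pentamer] = 0.0
    out.index.name = "pentamer"
    return out


def make_ranked_list(delta: pd.DataFrame) -> pd.Series:
    """Rank all pentamers by ΔPSI, descending; ties broken lexicographically
    (A < C < G < U) by pentamer so the ordering is deterministic."""
    s = delta["delta_psi"]
    order = sorted(s.index, key=lambda p: (-s[p], p))
    ranked = s.loc[order]
    ranked.name = "delta_psi"
    ranked.index.name = "pentamer"
    return ranked


def write_rnk(ranked: pd.Series, path) -> None:
    """Two tab-separated columns (name, metric), no header."""
    with open(path, "w") as fh:
        for name, value in ranked.items():
            fh.write(f"{name}\t{value:.6f}\n")


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["pentamer", "delta_psi"])
    s = pd.Series(df["delta_psi"].to_numpy(dtype=float),
                  index=[validate_pentamer(p) for p in df["pentamer"]],
                  name="delta_psi")
    s.index.name = "pentamer"
    return s


@dataclass(frozen=True)
class LibrarySummary:
    """Sign and threshold counts over the 1023 mutant pentamers."""

    n_positive: int
    n_negative: int
    n_zero: int
    n_above_threshold: int
    n_below_threshold: int
    threshold: float
    max_delta: float
    min_delta: float
    max_pentamer: str
    min_pentamer: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_library(delta: pd.DataFrame, threshold: float = 10.0,
                      ctx: LibraryContext | None = None) -> LibrarySummary:
    """Count stimulatory/inhibitory/neutral mutants at reporting precision.

    ΔPSI is rounded to 2 decimals before sign classification, since a zero
    ΔPSI is only meaningful at the precision the values are reported at.
    The wild-type pentamer (ΔPSI ≡ 0 by construction) is excluded.
    """
    ctx = ctx or LibraryContext()
    mut = delta.drop(index=ctx.wt_pentamer)
    d = mut["delta_psi"].round(REPORT_DECIMALS)
    return LibrarySummary(
        n_positive=int((d > 0).sum()),
        n_negative=int((d < 0).sum()),
        n_zero=int((d == 0).sum()),
        n_above_threshold=int((d > threshold).sum()),
        n_below_threshold=int((d < -threshold).sum()),
        threshold=float(threshold),
        max_delta=float(d.max()),
        min_delta=float(d.min()),
        max_pentamer=str(d.idxmax()),
        min_pentamer=str(d.idxmin()),
    )


def replicate_concordance(matrix: pd.DataFrame,
                          ctx: LibraryContext | None = None) -> dict:
    """Replicate reproducibility of the screen.

    Pearson r and least-squares R² between the two replicate mutant PSI
    vectors over all 1024 pentamers, plus the mean absolute between-replicate
    PSI difference for mutants and for the WT controls.
    """
    ctx = ctx or LibraryContext()
    matrix = validate_psi_matrix(matrix, ctx)
    pairs = _mut_wt_rows(matrix.index)
    if len(pairs) < 2:
        raise ValueError("replicate concordance needs at least 2 replicates")
    (mut1, wt1), (mut2, wt2) = pairs[:2]
    x = matrix.loc[mut1].to_numpy(dtype=float)
    y = matrix.loc[mut2].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        r = r2 = math.nan
        note = "correlation undefined: a replicate PSI vector is constant"
    else:
        r = float(stats.pearsonr(x, y).statistic)
        r2 = float(stats.linregress(x, y).rvalue ** 2)
        note = ""
    mut_mask = matrix.columns != ctx.wt_pentamer
    return {
        "pearson_r": r,
        "r_squared": r2,
        "mean_abs_diff_mut": float(np.abs(x - y)[mut_mask].mean()),
        "mean_abs_diff_wt": float(abs(matrix.loc[wt1].iloc[0] - matrix.loc[wt2].iloc[0])),
        "note": note,
    }
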