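"""Transcriptome-map track export.

The map pairs each isochore's GC level (plotted as positive values) with its
per-tissue length-normalized expression level plotted as negative values, so
the two tracks mirror each other around zero and high expression shows as
peaks in both.  The sign flip is applied at export only; the stored E_L is
preserved in a companion column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd


def map_track_frame(expr: pd.DataFrame, tissues: Sequence[str]) -> pd.DataFrame:
    """Map rows ordered by (chrom, start): coordinates, GC, and per tissue
    both E_L and its negated plotting track."""
    cols = ["chrom", "start", "end", "GC"]
    df = expr[cols].copy()
    df["name"] = expr.index
    for t in tissues:
        col = f"E_L_{t}"
        if col not in expr.columns:
            raise ValueError(
                f"tissue {t!r} has no expression column; available: "
                f"{sorted(c[4:] for c in expr.columns if c.startswith('E_L_'))}"
            )
        df[col] = expr[col]
        df[f"track_{t}"] = -expr[col]
    return df.sort_values(["chrom", "start"]).set_index("name")


def export_map_tracks(
    expr: pd.DataFrame,
    out_dir: str | Path,
    tissues: Sequence[str],
    bedgraph: bool = False,
) -> list[Path]:
    """Write one map TSV per chromosome (and optionally one BEDGRAPH per
    tissue track).  Undefined expression becomes an empty field."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = map_track_frame(expr, tissues)
    written: list[Path] = []
    for chrom, sub in frame.groupby("chrom", sort=True):
        path = out_dir / f"map_{chrom}.tsv"
        sub.to_csv(path, sep="\t", na_rep="")
        written.append(path)
    if bedgraph:
        for t in tissues:
            path = out_dir / f"track_{t}.bedgraph"
            with open(path, "w") as out:
                out.write(f'track type=bedGraph name="E_L {t} (negated)"\n')
                for _, row in frame.iterrows():
                    v = row[f"track_{t}"]
                    if pd.notna(v):
                        out.write(
                            f"{row['chrom']}\t{int(row['start'])}\t"
                            f"{int(row['end'])}\t{v:.6f}\n"
                        )
            written.append(path)
    return written


def read_map_tracks(out_dir: str | Path) -> pd.DataFrame:
    """Read back every per-chromosome map TSV into one frame (round-trip of
    :func:`export_map_tracks`)."""
    out_dir = Path(out_dir)
    parts = [
        pd.read_csv(p, sep="\t", index_col=0)
        for p in sorted(out_dir.glob("map_*.tsv"))
    ]
    if not parts:
        raise FileNotFoundError(f"no map_*.tsv files under {out_dir}")
    return pd.concat(parts).sort_values(["chrom", "start"])
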