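"""Expression-level arithmetic: qPCR, DE filtering, panel heatmap matrix.

Four small, exact computations used downstream of standard tooling:

* relative expression from qPCR threshold cycles by the dCt method,
  ``rel = 2 ** -(Ct_gene - Ct_reference)`` with technical replicates averaged
  before differencing (reference gene: GAPDH by convention);
* differential-expression classification of a finished (gene, log2FC, p, FDR)
  table: up if log2FC >= +1.5, down if log2FC <= -1.5, in both cases
  requiring p < 0.05 and FDR < 0.05 (fold-change bound inclusive, the
  significance bounds strict);
* overlap counts of up/down gene sets between two contrasts (Venn-diagram
  numbers);
* a per-column z-score matrix of panel-gene log2FC values for heatmap
  display, plus the marker-positivity percentage helper.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "relative_expression", "classify_de", "overlap_counts",
    "panel_zscore_matrix", "marker_positive_percentage", "load_calcium_panel",
]

REPLICATE_SD_WARN_CYCLES = 0.5


def relative_expression(ct: pd.DataFrame, reference_gene: str = "GAPDH") -> pd.DataFrame:
    """Relative expression 2^-dCt per (gene, sample).

    ``ct`` is long-format with columns gene, sample, ct (a replicate column
    is optional; technical replicates are averaged per gene and sample before
    differencing). dCt = mean Ct(gene) - mean Ct(reference, same sample).

    Returns columns gene, sample, delta_ct, rel_expr, high_replicate_sd —
    the last flags (gene, sample) pairs whose replicate SD exceeds
    0.5 cycles.
    """
    required = {"gene", "sample", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("non-finite Ct values")
    grouped = ct.groupby(["gene", "sample"])["ct"].agg(["mean", "std", "count"])
    grouped["std"] = grouped["std"].fillna(0.0)
    samples = ct["sample"].unique()
    ref = grouped.xs(reference_gene, level="gene")["mean"] \
        if reference_gene in ct["gene"].values else None
    rows = []
    for (gene, sample), row in grouped.iterrows():
        if gene == reference_gene:
            continue
        if ref is None or sample not in ref.index:
            raise ValueError(
                f"reference gene '{reference_gene}' missing for sample '{sample}'")
        delta_ct = row["mean"] - ref.loc[sample]
        high_sd = bool(row["std"] > REPLICATE_SD_WARN_CYCLES)
        if high_sd:
            warnings.warn(
                f"replicate SD {row['std']:.2f} cycles > "
                f"{REPLICATE_SD_WARN_CYCLES} for {gene}/{sample}")
        rows.append({"gene": gene, "sample": sample, "delta_ct": delta_ct,
                     "rel_expr": 2.0 ** -delta_ct, "high_replicate_sd": high_sd})
    order = {s: i for i, s in enumerate(samples)}
    out = pd.DataFrame(rows, columns=["gene", "sample", "delta_ct",
                                      "rel_expr", "high_replicate_sd"])
    return out.sort_values(["gene", "sample"],
                           key=lambda s: s.map(order) if s.name == "sample" else s
                           ).reset_index(drop=True)


def classify_de(de: pd.DataFrame, up_lfc: float = 1.5, down_lfc: float = -1.5,
                p_max: float = 0.05, fdr_max: float = 0.05) -> pd.Series:
    """Label each gene up / down / ns.

    up: log2fc >= up_lfc and p < p_max and fdr < fdr_max;
    down: log2fc <= down_lfc with the same significance requirement;
    otherwise ns. The fold-change bounds are inclusive, p/FDR strict.
    """
    required = {"gene", "log2fc", "p", "fdr"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    if de["gene"].duplicated().any():
        dup = de.loc[de["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicated gene id '{dup}'")
    bad = ((de["p"] < 0) | (de["p"] > 1) | (de["fdr"] < 0) | (de["fdr"] > 1))
    if bad.any():
        raise ValueError("p and fdr must lie in [0, 1]")
    sig = (de["p"] < p_max) & (de["fdr"] < fdr_max)
    labels = np.where(sig & (de["log2fc"] >= up_lfc), "up",
                      np.where(sig & (de["log2fc"] <= down_lfc), "down", "ns"))
    return pd.Series(labels, index=de["gene"].to_numpy(), name="label")


def overlap_counts(labels_a: pd.Series, labels_b: pd.Series) -> dict[str, int]:
    """Venn counts of up- and down-regulated gene sets between two contrasts."""
    for name, s in (("A", labels_a), ("B", labels_b)):
        if s.index.duplicated().any():
            raise ValueError(f"duplicated gene ids in contrast {name}")
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("contrasts cover different gene universes")
    out = {}
    for direction in ("up", "down"):
        a = set(labels_a.index[labels_a == direction])
        b = set(labels_b.index[labels_b == direction])
        out[f"{direction}_common"] = len(a & b)
        out[f"{direction}_only_a"] = len(a - b)
        out[f"{direction}_only_b"] = len(b - a)
    return out


def panel_zscore_matrix(log2fc: pd.DataFrame, panel: list[str],
                        clip: float | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Column z-scores of panel-gene log2FC values (heatmap matrix).

    ``log2fc`` is genes (index) x contrasts (columns). Per column,
    z = (x - mean) / population SD over the panel genes present. Panel genes
    absent from the table are returned (not silently dropped). A constant
    column yields zeros with a warning. ``clip`` symmetrically clips for
    display (e.g. 1.0 for a -1..+1 colour range); off by default.
    """
    panel = list(panel)
    missing = [g for g in panel if g not in log2fc.index]
    present = [g for g in panel if g in log2fc.index]
    if not present:
        raise ValueError("no panel genes present in the table")
    sub = log2fc.loc[present].astype(float)
    z = pd.DataFrame(index=sub.index, columns=sub.columns, dtype=float)
    for col in sub.columns:
        x = sub[col].to_numpy()
        sd = float(np.std(x, ddof=0))
        if sd == 0:
            warnings.warn(f"column '{col}' is constant; z-scores set to 0")
            z[col] = 0.0
        else:
            z[col] = (x - float(np.mean(x))) / sd
    if clip is not None:
        z = z.clip(-clip, clip)
    return z, missing


def marker_positive_percentage(positive: int, total: int) -> float:
    """Percentage of marker-positive cells, truncated to two decimals.

    Truncation (not rounding) matches the reporting convention of
    immunocytochemistry counts such as 91/283 -> 32.15%.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= positive <= total:
        raise ValueError("need 0 <= positive <= total")
    pct = 100.0 * positive / total
    return math.floor(round(pct * 100, 6)) / 100.0


def load_calcium_panel() -> list[str]:
    """The bundled neuronal calcium-signalling gene panel (109 HGNC symbols).

    The membership is a synthetic, user-replaceable stand-in assembled from
    canonical calcium-toolkit families (VGCC subunits, ionotropic and
    metabotropic glutamate receptors, phospholipases, IP3/ryanodine
    receptors, SERCA/PMCA/NCX pumps and exchangers, STIM/Orai, calmodulin
    kinases, calcium-binding proteins); replace the packaged
    ``calcium_panel.txt`` to use a study-specific list.
    """
    text = (resources.files("neurocal") / "data" / "calcium_panel.txt").read_text()
    genes = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    return genes
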