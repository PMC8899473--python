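"""TPM computation and housekeeping-relative toxin expression."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hkg import HkgPanel


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    contig_id: str
    category: str  # toxin | hkg | other
    tpm: float
    log2_fold_vs_hkg: Optional[float] = None

    def __post_init__(self):
        if self.tpm < 0:
            raise ExpressionError(f"negative TPM for {self.contig_id!r}")
        if self.category not in ("toxin", "hkg", "other"):
            raise ExpressionError(f"unknown category {self.category!r}")


def tpm_from_counts(counts, effective_lengths) -> np.ndarray:
    """Standard TPM: per-length rates scaled to sum to 1e6."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ExpressionError("counts and lengths differ in shape")
    if np.any(lengths <= 0):
        raise ExpressionError("effective lengths must be positive")
    if np.any(counts < 0):
        raise ExpressionError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise ExpressionError("all counts are zero")
    return 1e6 * rates / total


def hkg_fold_change(
    toxin_tpm: float, hkg_tpms: Sequence[float], mean: str = "arithmetic"
) -> Optional[float]:
    """log2(toxin TPM / mean HKG TPM) within one transcriptome.

    Returns ``None`` for a zero toxin TPM (the fold change is undefined, and
    reports should flag such toxins as absent rather than carry -inf).
    """
    hkg_tpms = list(hkg_tpms)
    if not hkg_tpms:
        raise ExpressionError("no HKG TPM values supplied")
    if mean == "arithmetic":
        baseline = sum(hkg_tpms) / len(hkg_tpms)
    elif mean == "geometric":
        if any(x <= 0 for x in hkg_tpms):
            raise ExpressionError("geometric mean requires positive HKG TPMs")
        baseline = math.exp(sum(math.log(x) for x in hkg_tpms) / len(hkg_tpms))
    else:
        raise ExpressionError(f"unknown mean {mean!r}")
    if baseline <= 0:
        raise ExpressionError("mean HKG TPM must be positive")
    if toxin_tpm < 0:
        raise ExpressionError("toxin TPM must be non-negative")
    if toxin_tpm == 0:
        return None
    return math.log2(toxin_tpm / baseline)


def expression_report(
    records: pd.DataFrame,
    panel: Optional[HkgPanel],
    toxin_ids: Sequence[str],
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-(sample, toxin) TPM, HKG-mean TPM and log2 fold change.

    Rows are sorted by descending fold within each sample and ranked; the
    top toxin per sample carries ``is_top=True`` (the prioritization lead).
    ``panel`` selects the HKG contigs per sample; with ``panel=None`` all
    rows whose category is "hkg" are used.
    """
    required = {"sample_id", "contig_id", "tpm"}
    if not required <= set(records.columns):
        raise ExpressionError(f"records table needs columns {sorted(required)}")
    toxin_ids = list(toxin_ids)
    out_rows = []
    for sample, grp in records.groupby("sample_id", sort=True):
        tpm_of = dict(zip(grp["contig_id"], grp["tpm"].astype(float)))
        if panel is not None:
            hkg_tpms = []
            for gene in sorted(panel.gene_labels):
                contig = panel.representatives.get((sample, gene))
                if contig is None or contig not in tpm_of:
                    raise ExpressionError(
                        f"sample {sample!r}: missing HKG value for gene {gene!r}"
                    )
                hkg_tpms.append(tpm_of[contig])
        else:
            if "category" not in grp.columns:
                raise ExpressionError("no panel given and no category column")
            hkg_tpms = list(grp.loc[grp["category"] == "hkg", "tpm"].astype(float))
        if not hkg_tpms:
            raise ExpressionError(f"sample {sample!r} has no HKG expression values")
        hkg_mean = sum(hkg_tpms) / len(hkg_tpms)
        for toxin in toxin_ids:
            if toxin not in tpm_of:
                continue
            fold = hkg_fold_change(tpm_of[toxin], hkg_tpms, mean=mean)
            out_rows.append(
                {
                    "sample_id": sample,
                    "contig_id": toxin,
                    "tpm": tpm_of[toxin],
                    "hkg_mean_tpm": hkg_mean,
                    "log2_fold_vs_hkg": fold,
                    "absent": fold is None,
                }
            )
    df = pd.DataFrame(
        out_rows,
        columns=[
            "sample_id",
            "contig_id",
            "tpm",
            "hkg_mean_tpm",
            "log2_fold_vs_hkg",
            "absent",
        ],
    )
    if df.empty:
        return df.assign(rank=pd.Series(dtype=int), is_top=pd.Series(dtype=bool))
    df = df.sort_values(
        ["sample_id", "log2_fold_vs_hkg", "contig_id"],
        ascending=[True, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("sample_id").cumcount() + 1
    df["is_top"] = df["rank"] == 1
    return df
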