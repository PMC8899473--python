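"""Housekeeping-gene panel construction from per-sample contig annotations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .io_formats import SequenceRecord, write_fasta


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatedContig:
    sample_id: str
    contig_id: str
    gene_label: str
    e_value: float
    tpm: float

    def __post_init__(self):
        if self.e_value < 0:
            raise PanelError(f"negative e-value for {self.contig_id!r}")
        if self.tpm < 0:
            raise PanelError(f"negative TPM for {self.contig_id!r}")


@dataclass
class HkgPanel:
    gene_labels: frozenset
    representatives: dict  # (sample_id, gene_label) -> contig_id
    sample_ids: tuple

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def size(self) -> int:
        return len(self.gene_labels)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "gene_label": g, "contig_id": c}
            for (s, g), c in sorted(self.representatives.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "gene_label", "contig_id"])


ContigInput = Union[pd.DataFrame, Iterable[AnnotatedContig]]


def _as_frame(contigs: ContigInput) -> pd.DataFrame:
    if isinstance(contigs, pd.DataFrame):
        df = contigs.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "contig_id": c.contig_id,
                    "gene_label": c.gene_label,
                    "e_value": c.e_value,
                    "tpm": c.tpm,
                }
                for c in contigs
            ]
        )
    required = {"sample_id", "contig_id", "gene_label", "e_value", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"annotation table missing columns: {sorted(missing)}")
    df["e_value"] = df["e_value"].astype(float)
    df["tpm"] = df["tpm"].astype(float)
    return df


def filter_hits(contigs: ContigInput, e_threshold: float = 1e-4) -> pd.DataFrame:
    """Keep annotation hits with e-value strictly below ``e_threshold``."""
    if e_threshold <= 0:
        raise PanelError("e_threshold must be positive")
    df = _as_frame(contigs)
    return df[df["e_value"] < e_threshold].reset_index(drop=True)


def build_panel(filtered_contigs: ContigInput) -> HkgPanel:
    """Intersect gene labels over samples; pick one representative contig
    per (sample, gene): smallest e-value, then largest TPM, then smallest
    contig id.  Row order never affects the result.
    """
    df = _as_frame(filtered_contigs)
    if df.empty:
        raise PanelError("no annotated contigs — at least one sample required")
    samples = tuple(sorted(df["sample_id"].unique()))
    per_sample = {
        s: set(df.loc[df["sample_id"] == s, "gene_label"]) for s in samples
    }
    shared = set.intersection(*per_sample.values())
    if not shared:
        warnings.warn("no genes shared by all samples — empty panel", stacklevel=2)

    reps: dict = {}
    sub = df[df["gene_label"].isin(shared)]
    sub = sub.sort_values(
        ["sample_id", "gene_label", "e_value", "tpm", "contig_id"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    for (sample, gene), grp in sub.groupby(["sample_id", "gene_label"], sort=True):
        reps[(sample, gene)] = grp.iloc[0]["contig_id"]
    return HkgPanel(
        gene_labels=frozenset(shared), representatives=reps, sample_ids=samples
    )


def export_gene_sets(
    panel: HkgPanel,
    sequences: Mapping,
    out_dir,
) -> list[Path]:
    """Write one FASTA per panel gene, one record per sample with ids
    ``sample|contig``.  ``sequences`` maps (sample_id, contig_id) to residue
    strings or :class:`SequenceRecord` objects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for gene in sorted(panel.gene_labels):
        records = []
        for sample in panel.sample_ids:
            contig = panel.representatives[(sample, gene)]
            seq = sequences.get((sample, contig))
            if seq is None:
                raise PanelError(f"missing sequence for sample {sample!r}, gene {gene!r}")
            residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
            records.append(SequenceRecord(id=f"{sample}|{contig}", residues=residues))
        path = out_dir / f"{gene}.fasta"
        write_fasta(records, path)
        paths.append(path)
    return paths


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _as_frame(df)


def write_annotation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
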