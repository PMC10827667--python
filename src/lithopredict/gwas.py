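"""Overlap of a DEG symbol list with per-study GWAS-reported gene sets.

Pure set logic on user-provided study files: symbols are compared
upper-cased with surrounding whitespace stripped; no alias resolution.
Study files are CSV with header ``accession,title,total_reported,genes``
where ``genes`` is semicolon-delimited.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["StudyGeneSet", "read_study_sets", "overlap", "normalize_symbol"]


@dataclass
class StudyGeneSet:
    study_accession: str
    title: str
    reported_genes: frozenset[str]
    total_reported: int

    def __post_init__(self) -> None:
        if not self.study_accession:
            raise ValueError("study accession must be non-empty")
        self.reported_genes = frozenset(
            normalize_symbol(g) for g in self.reported_genes if str(g).strip()
        )
        if self.total_reported < len(self.reported_genes):
            raise ValueError(
                f"study {self.study_accession}: total_reported "
                f"{self.total_reported} < {len(self.reported_genes)} listed genes"
            )


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def read_study_sets(path: str | Path) -> list[StudyGeneSet]:
    studies = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"accession", "title", "total_reported", "genes"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                studies.append(
                    StudyGeneSet(
                        study_accession=row["accession"].strip(),
                        title=row["title"].strip(),
                        reported_genes=frozenset(
                            g for g in row["genes"].split(";") if g.strip()
                        ),
                        total_reported=int(row["total_reported"]),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return studies


def overlap(deg_symbols, studies: list[StudyGeneSet]) -> pd.DataFrame:
    """Per-study intersection with a DEG symbol set.

    Returns one row per study with columns ``accession, title,
    overlapping_genes (sorted, ';'-joined), n_overlap, total_reported``;
    studies with empty overlap are still listed (n_overlap = 0).
    """
    degs = {normalize_symbol(s) for s in deg_symbols}
    degs.discard("")
    if not degs:
        raise ValueError("empty DEG symbol set")
    rows = []
    for st in studies:
        inter = sorted(degs & st.reported_genes)
        rows.append(
            {
                "accession": st.study_accession,
                "title": st.title,
                "overlapping_genes": ";".join(inter),
                "n_overlap": len(inter),
                "total_reported": st.total_reported,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["accession", "title", "overlapping_genes", "n_overlap", "total_reported"],
    )
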