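"""OTU table container and classic tab-separated I/O.

The on-disk layout is the QIIME-classic dialect: taxa as rows, samples as
columns, a leading ``#OTU ID`` header and a trailing ``taxonomy`` column with
semicolon-delimited Greengenes-style lineage strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")
RANK_PREFIXES = {"phylum": "p__", "class": "c__", "order": "o__",
                 "family": "f__", "genus": "g__"}


@dataclass
class OtuTable:
    """Sample-by-taxon count matrix with per-taxon lineage strings.

    ``counts`` is indexed by sample ID with taxon IDs as columns;
    ``taxonomy`` maps taxon ID to a lineage string such as
    ``k__Bacteria;p__P01;c__C02;o__O03;f__F04;g__G05``.
    ``rarefied_depth`` is None for raw tables.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series = field(default=None)
    rarefied_depth: int | None = None

    def __post_init__(self) -> None:
        if self.taxonomy is None:
            self.taxonomy = pd.Series("", index=self.counts.columns)
        self.taxonomy = self.taxonomy.reindex(self.counts.columns).fillna("")
        if (self.counts.values < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if self.rarefied_depth is not None:
            sums = self.counts.sum(axis=1)
            if not (sums == self.rarefied_depth).all():
                raise ValueError("rarefied table has samples not at depth")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], self.taxonomy,
                        self.rarefied_depth)

    def subset_taxa(self, taxon_ids) -> "OtuTable":
        return OtuTable(self.counts[list(taxon_ids)],
                        self.taxonomy.loc[list(taxon_ids)],
                        self.rarefied_depth)

    def lineage_at(self, rank: str) -> pd.Series:
        """Taxon-level name at ``rank``, with unassigned levels grouped as
        ``unclassified-<nearest assigned parent>``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        want = RANKS.index(rank)
        out = {}
        for otu, lineage in self.taxonomy.items():
            fields = [f.strip() for f in str(lineage).split(";")]
            # drop a leading kingdom field if present
            levels = [f for f in fields if not f.startswith("k__")]
            name = None
            if want < len(levels):
                cand = levels[want]
                prefix = RANK_PREFIXES[rank]
                if cand.startswith(prefix) and len(cand) > len(prefix):
                    name = cand
            if name is None:
                parent = ""
                for lvl in levels[:want]:
                    if len(lvl.split("__", 1)[-1]) > 0:
                        parent = lvl
                out[otu] = f"unclassified-{parent}" if parent else "unclassified"
            else:
                out[otu] = name
        return pd.Series(out).reindex(self.counts.columns)

    # ---- I/O -------------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        df = self.counts.T.copy()
        df.index.name = "#OTU ID"
        df["taxonomy"] = self.taxonomy.reindex(df.index).values
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path,
                 rarefied_depth: int | None = None) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "taxonomy" in df.columns:
            taxonomy = df["taxonomy"].fillna("").astype(str)
            df = df.drop(columns=["taxonomy"])
        else:
            taxonomy = pd.Series("", index=df.index)
        counts = df.T.astype(np.int64)
        counts.index.name = "sample_id"
        return cls(counts, taxonomy, rarefied_depth)
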