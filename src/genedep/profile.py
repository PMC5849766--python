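"""Paired copy-number / expression cohort container.

The pipeline operates on a *gene-centric* view of a tumor cohort: one
absolute-copy-number-like matrix and one log2-like expression matrix over a
shared gene and sample index, plus per-sample clinical metadata (molecular
group, recurrence status and time).  Copy number is centered at 2 (diploid);
a "gain" in this package means a value at or above the gain threshold
(default 2.38).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

#: Recognised sample groups.  ``TNBC`` are ER-/PR-/HER2- tumors, ``HER2``
#: are HER2+/ER- tumors, ``ER`` are HER2-/ER+ tumors and ``normal`` are
#: normal breast epithelium controls.
GROUPS = ("TNBC", "HER2", "ER", "normal")


@dataclass
class GeneCentricProfile:
    """Paired CN and expression matrices with sample metadata.

    Parameters
    ----------
    cn
        Gene-by-sample copy-number matrix (absolute-copy-number-like scale,
        diploid = 2).  Normal samples may carry ``NaN`` copy number.
    gex
        Gene-by-sample expression matrix (log2-like scale).
    samples
        Metadata indexed by sample id with at least a ``group`` column
        (values from :data:`GROUPS`); optional ``recurrence`` (0/1) and
        ``recurrence_time`` columns for outcome analyses.
    truth
        Optional generator-reported ground truth (planted gene sets etc.);
        empty for real data.
    """

    cn: pd.DataFrame
    gex: pd.DataFrame
    samples: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cn.index.duplicated().any() or self.gex.index.duplicated().any():
            raise ValueError("duplicated gene identifiers")
        if not self.cn.index.equals(self.gex.index):
            raise ValueError("cn and gex must share the same gene index")
        if not self.cn.columns.equals(self.gex.columns):
            raise ValueError("cn and gex must share the same sample columns")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata requires a 'group' column")
        missing = self.cn.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples missing metadata: {list(missing)[:5]}")
        unknown = set(self.samples["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown sample groups: {sorted(unknown)}")

    @property
    def genes(self) -> pd.Index:
        return self.cn.index

    def group_samples(self, *groups: str) -> list[str]:
        """Sample ids belonging to any of the given groups, in matrix order."""
        members = set(
            self.samples.index[self.samples["group"].isin(groups)]
        )
        return [s for s in self.cn.columns if s in members]

    @property
    def tnbc_samples(self) -> list[str]:
        return self.group_samples("TNBC")

    @property
    def normal_samples(self) -> list[str]:
        return self.group_samples("normal")

    def subset_genes(self, genes: Sequence[str]) -> "GeneCentricProfile":
        genes = list(genes)
        return GeneCentricProfile(
            cn=self.cn.loc[genes],
            gex=self.gex.loc[genes],
            samples=self.samples,
            truth=self.truth,
        )
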