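"""Core in-memory containers shared by every pipeline stage.

A :class:`CohortPanel` bundles the alt-allele dosage matrix with per-variant
and per-sample metadata.  Dosages live in ``[0, 2]``; missing calls are
``numpy.nan``.  Per-variant QC statistics (MAF, missing rate, HWE p,
heterozygosity excess) are computed lazily by :mod:`gardscan.qc` and stored
back on the variant table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every variant table carries.  Imputation-quality columns
#: (impute_r2, iam_hwe, hiq) are NaN for genotyped variants.
VARIANT_COLUMNS = [
    "id", "chrom", "pos", "ref", "alt", "source",
    "maf", "miss_rate", "hwe_p", "het_excess",
    "impute_r2", "iam_hwe", "hiq",
]

SAMPLE_COLUMNS = ["id", "status", "sex", "age", "smoking",
                  "pc1", "pc2", "pc3", "pc4"]

SMOKING_LEVELS = ("never", "former", "current")


@dataclass
class CohortPanel:
    """Dosage matrix plus variant and sample metadata.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant; at least the columns in :data:`VARIANT_COLUMNS`
        that are known at construction time (missing ones are added as NaN).
    samples : pandas.DataFrame
        One row per sample with :data:`SAMPLE_COLUMNS`.
    dosage : numpy.ndarray
        ``(n_samples, n_variants)`` float array of alt-allele dosage in
        ``[0, 2]``; NaN marks a missing call.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True).copy()
        self.samples = self.samples.reset_index(drop=True).copy()
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                self.variants[col] = np.nan
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"]
            raise ValueError(f"duplicate variant ids: {list(dups.unique())[:5]}")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise ValueError(f"{int(bad)} dosage values outside [0, 2]")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def status(self) -> np.ndarray:
        """Binary outcome vector: 1 = case, 0 = control."""
        return (self.samples["status"].to_numpy() == "case").astype(float)

    def covariate_matrix(self, include_age: bool = False) -> np.ndarray:
        """Design columns for the adjusted model: sex, smoking (former,
        current vs never), 4 PCs, optionally standardized age.  No
        intercept column (fitters add their own)."""
        s = self.samples
        cols = [
            (s["sex"].to_numpy() == "male").astype(float),
            (s["smoking"].to_numpy() == "former").astype(float),
            (s["smoking"].to_numpy() == "current").astype(float),
            s["pc1"].to_numpy(float),
            s["pc2"].to_numpy(float),
            s["pc3"].to_numpy(float),
            s["pc4"].to_numpy(float),
        ]
        if include_age:
            age = s["age"].to_numpy(float)
            sd = age.std()
            cols.append((age - age.mean()) / (sd if sd > 0 else 1.0))
        return np.column_stack(cols)

    def subset_variants(self, keep_ids) -> "CohortPanel":
        """Panel restricted to the given variant ids (original order kept)."""
        keep = set(keep_ids)
        mask = self.variants["id"].isin(keep).to_numpy()
        return CohortPanel(
            variants=self.variants.loc[mask],
            samples=self.samples,
            dosage=self.dosage[:, mask],
        )

    def variant_index(self, vid: str) -> int:
        idx = np.flatnonzero((self.variants["id"] == vid).to_numpy())
        if idx.size == 0:
            raise KeyError(vid)
        return int(idx[0])
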