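"""In-memory containers for metabolomics feature tables and genotype panels.

Two tabular containers travel through the whole pipeline:

* :class:`FeatureTable` — a samples × features abundance matrix with sample
  metadata (case/control group, study set, age, blood-draw date), feature
  annotation (m/z, formula, chemical super-class) and per-feature QC-injection
  detection fractions.
* :class:`GenotypePanel` — a samples × SNP allele-count matrix (0/1/2 with
  missing) plus sample metadata, the input to SNP QC, GWAS and genetic risk
  scores.

Both round-trip losslessly through plain TSV files so every pipeline stage can
be re-run independently from its on-disk artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "set", "group", "age", "draw_date"]


@dataclass
class FeatureTable:
    """Samples × features abundance table with metadata and annotation.

    Parameters
    ----------
    abundance
        Non-negative abundance matrix, index = sample ids, columns = feature
        ids.  Missing values are allowed (NaN).
    samples
        One row per sample with at least the columns in
        :data:`SAMPLE_COLUMNS`; index aligned with ``abundance``.
    features
        One row per feature: ``feature_id``, ``hmdb_like_id``, ``mz``,
        ``formula``, ``super_class`` (NaN for unidentified features) and
        ``qc_detection`` — fraction of QC injections in which the feature was
        detected.
    qc_replicates
        Optional replicate QC-injection abundance matrix (replicates ×
        features) used for %RSD assay-precision reporting.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    qc_replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.abundance.index) != list(self.samples.index):
            raise ValueError("abundance rows and sample metadata are misaligned")
        if list(self.abundance.columns) != list(self.features.index):
            raise ValueError("abundance columns and feature annotation are misaligned")
        vals = self.abundance.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundances must be non-negative where present")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    @property
    def qc_detection(self) -> pd.Series:
        return self.features["qc_detection"]

    @property
    def groups(self) -> pd.Series:
        """Case/control labels aligned with the abundance rows."""
        return self.samples["group"]

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        return FeatureTable(
            abundance=self.abundance.loc[:, feature_ids],
            samples=self.samples,
            features=self.features.loc[feature_ids],
            qc_replicates=None
            if self.qc_replicates is None
            else self.qc_replicates.loc[:, feature_ids],
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        sample_ids = list(sample_ids)
        return FeatureTable(
            abundance=self.abundance.loc[sample_ids],
            samples=self.samples.loc[sample_ids],
            features=self.features,
            qc_replicates=self.qc_replicates,
        )

    # ------------------------------------------------------------------ IO
    def write(self, directory: str | Path, prefix: str) -> dict[str, Path]:
        """Write abundance+metadata, annotation and QC replicates as TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        wide = pd.concat([self.samples[SAMPLE_COLUMNS[1:]], self.abundance], axis=1)
        wide.insert(0, "sample_id", self.samples.index)
        paths["abundance"] = directory / f"{prefix}_abundance.tsv"
        wide.to_csv(paths["abundance"], sep="\t", index=False)

        ann = self.features.reset_index(names="feature_id")
        paths["features"] = directory / f"{prefix}_features.tsv"
        ann.to_csv(paths["features"], sep="\t", index=False)

        if self.qc_replicates is not None:
            paths["qc_replicates"] = directory / f"{prefix}_qc_replicates.tsv"
            self.qc_replicates.to_csv(paths["qc_replicates"], sep="\t",
                                      index_label="replicate_id")
        return paths

    @classmethod
    def read(cls, directory: str | Path, prefix: str) -> "FeatureTable":
        directory = Path(directory)
        wide = pd.read_csv(directory / f"{prefix}_abundance.tsv", sep="\t")
        wide = wide.set_index("sample_id")
        samples = wide[SAMPLE_COLUMNS[1:]].copy()
        abundance = wide.drop(columns=SAMPLE_COLUMNS[1:])
        features = pd.read_csv(directory / f"{prefix}_features.tsv", sep="\t")
        features = features.set_index("feature_id")
        qc_path = directory / f"{prefix}_qc_replicates.tsv"
        qc = None
        if qc_path.exists():
            qc = pd.read_csv(qc_path, sep="\t").set_index("replicate_id")
        return cls(abundance=abundance, samples=samples, features=features,
                   qc_replicates=qc)


@dataclass
class GenotypePanel:
    """Samples × SNP additive allele counts with sample metadata.

    ``genotypes`` holds counts of the coded allele in {0, 1, 2} as floats with
    NaN for missing calls, in the spirit of a PLINK ``.raw`` export.
    ``samples`` carries ``group`` (case/control), ``age`` and ``cohort``
    ("set1"/"set2" for the nested case-control sets, "pool" for additional
    genotyped subjects used only to estimate GWAS weights).
    """

    genotypes: pd.DataFrame
    samples: pd.DataFrame
    qc_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.genotypes.index) != list(self.samples.index):
            raise ValueError("genotype rows and sample metadata are misaligned")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("allele counts must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def snp_missing_rate(self) -> pd.Series:
        return self.genotypes.isna().mean(axis=0)

    def sample_missing_rate(self) -> pd.Series:
        return self.genotypes.isna().mean(axis=1)

    def minor_allele_frequency(self) -> pd.Series:
        """Frequency of the rarer allele per SNP, ignoring missing calls."""
        freq = self.genotypes.mean(axis=0) / 2.0
        return pd.Series(np.minimum(freq, 1.0 - freq), index=self.genotypes.columns)

    def coded_allele_frequency(self) -> pd.Series:
        return self.genotypes.mean(axis=0) / 2.0

    def subset_snps(self, snp_ids) -> "GenotypePanel":
        return GenotypePanel(self.genotypes.loc[:, list(snp_ids)], self.samples,
                             dict(self.qc_log))

    def subset_samples(self, sample_ids) -> "GenotypePanel":
        sample_ids = list(sample_ids)
        return GenotypePanel(self.genotypes.loc[sample_ids],
                             self.samples.loc[sample_ids], dict(self.qc_log))

    # ------------------------------------------------------------------ IO
    def write(self, directory: str | Path, prefix: str) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        geno = self.genotypes.copy()
        geno.insert(0, "sample_id", geno.index)
        paths["genotypes"] = directory / f"{prefix}_genotypes.raw.tsv"
        geno.to_csv(paths["genotypes"], sep="\t", index=False, na_rep="NA")
        meta = self.samples.reset_index(names="sample_id")
        paths["samples"] = directory / f"{prefix}_gsamples.tsv"
        meta.to_csv(paths["samples"], sep="\t", index=False)
        return paths

    @classmethod
    def read(cls, directory: str | Path, prefix: str) -> "GenotypePanel":
        directory = Path(directory)
        geno = pd.read_csv(directory / f"{prefix}_genotypes.raw.tsv", sep="\t",
                           na_values="NA").set_index("sample_id")
        samples = pd.read_csv(directory / f"{prefix}_gsamples.tsv",
                              sep="\t").set_index("sample_id")
        return cls(genotypes=geno.astype(float), samples=samples)
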