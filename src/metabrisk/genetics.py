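"""SNP quality control, age-adjusted logistic GWAS, and genetic risk scores.

QC follows the standard array-genotyping sequence, in a documented order:
drop SNPs with > 5% missing calls, then samples with > 5% missing calls,
then SNPs with minor allele frequency < 0.05, then SNPs out of
Hardy-Weinberg equilibrium at p < 1e-6 by the exact (conditional on allele
counts) test in the PLINK convention.

Association is a per-SNP additive logistic regression of case status on
allele count adjusting for age, fitted by iteratively reweighted least
squares, with Wald p-values; complete separation is flagged rather than
reported.  SNPs below the selection p threshold (5e-5 by default) define the
risk panel, and the genetic risk score of subject i is

    GRS_i = sum_j (risk-allele count of SNP j) * weight_j,

with the GWAS log-odds as the weight, the higher-risk allele as the counted
allele, and missing genotypes contributing the mean count 2 * f_risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, exp

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import GenotypePanel


# ----------------------------------------------------------------- HWE exact
def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg p-value conditional on allele counts.

    Sums the probabilities of all heterozygote counts (with the parity fixed
    by the minor-allele count) whose conditional probability does not exceed
    that of the observed configuration — the standard two-sided exact test.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het

    # log P(het = h | n, rare) up to a shared constant
    def logprob(h: int) -> float:
        homr = (rare - h) // 2
        homc = n - h - homr
        return (h * log(2.0) - lgamma(h + 1) - lgamma(homr + 1)
                - lgamma(homc + 1))

    hs = range(rare % 2, rare + 1, 2)
    logs = {h: logprob(h) for h in hs if (rare - h) // 2 >= 0
            and n - h - (rare - h) // 2 >= 0}
    m = max(logs.values())
    probs = {h: exp(v - m) for h, v in logs.items()}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(p, 1.0)


def hwe_pvalues(panel: GenotypePanel) -> pd.Series:
    """Exact HWE p per SNP from observed genotype counts."""
    out = {}
    for snp in panel.snp_ids:
        g = panel.genotypes[snp].dropna()
        out[snp] = hwe_exact_p(int((g == 1).sum()), int((g == 0).sum()),
                               int((g == 2).sum()))
    return pd.Series(out)


# ------------------------------------------------------------------------ QC
def snp_qc(panel: GenotypePanel, snp_missing_max: float = 0.05,
           sample_missing_max: float = 0.05, maf_min: float = 0.05,
           hwe_min_p: float = 1e-6) -> GenotypePanel:
    """Sequential genotype QC with per-filter removal counts in ``qc_log``.

    Filter order (each applied to the survivors of the previous): SNP missing
    rate, sample missing rate, minor allele frequency, exact HWE.  Raises if
    no SNP survives.
    """
    if panel.n_snps == 0 or panel.n_samples == 0:
        raise ValueError("empty genotype panel")
    log_counts: dict[str, int] = {}

    keep_snps = panel.snp_missing_rate() <= snp_missing_max
    log_counts["snp_missing"] = int((~keep_snps).sum())
    p1 = panel.subset_snps(panel.genotypes.columns[keep_snps])

    keep_samples = p1.sample_missing_rate() <= sample_missing_max
    log_counts["sample_missing"] = int((~keep_samples).sum())
    p2 = p1.subset_samples(p1.genotypes.index[keep_samples])

    keep_maf = p2.minor_allele_frequency() >= maf_min
    log_counts["maf"] = int((~keep_maf).sum())
    p3 = p2.subset_snps(p2.genotypes.columns[keep_maf])

    hwe = hwe_pvalues(p3)
    keep_hwe = hwe >= hwe_min_p
    log_counts["hwe"] = int((~keep_hwe).sum())
    p4 = p3.subset_snps(p3.genotypes.columns[keep_hwe])

    if p4.n_snps == 0:
        raise ValueError(f"all SNPs removed by QC; per-filter counts: {log_counts}")
    p4.qc_log = log_counts
    return p4


# ---------------------------------------------------------------------- GWAS
def gwas_logistic(panel: GenotypePanel, case_labels: pd.Series | None = None,
                  age: pd.Series | None = None) -> pd.DataFrame:
    """Per-SNP additive logistic regression of case status adjusted for age.

    Returns one row per SNP: beta (log odds per coded allele), se, p, n and a
    ``flagged`` column set where the fit showed separation or failed to
    converge (p is then missing).
    """
    labels = case_labels if case_labels is not None else panel.samples["group"]
    y_all = (labels == "case").astype(float) if labels.dtype == object else \
        labels.astype(float)
    age_all = age if age is not None else panel.samples["age"]
    rows = []
    for snp in panel.snp_ids:
        g = panel.genotypes[snp]
        ok = g.notna().to_numpy()
        yv = y_all.to_numpy()[ok]
        X = sm.add_constant(np.column_stack([g.to_numpy()[ok],
                                             age_all.to_numpy(dtype=float)[ok]]))
        flagged = False
        beta = se = pval = np.nan
        try:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(yv, X, family=sm.families.Binomial()).fit(maxiter=50)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            pval = float(fit.pvalues[1])
            if not np.isfinite(se) or abs(beta) > 15 or se > 50:
                flagged, pval = True, np.nan   # separation signature
        except Exception:
            flagged = True
        rows.append({"snp_id": snp, "beta": beta, "se": se, "p_value": pval,
                     "n": int(ok.sum()), "flagged": flagged})
    return pd.DataFrame(rows).set_index("snp_id")


def select_grs_weights(gwas: pd.DataFrame, panel: GenotypePanel,
                       p_threshold: float = 5e-5) -> pd.DataFrame:
    """Risk-SNP weights from GWAS results below the selection p threshold.

    The risk allele is the coded allele when its log-odds is positive and the
    other allele otherwise, so every weight is a positive log-odds.  The
    risk-allele frequency (for mean imputation of missing genotypes) is taken
    from the panel.
    """
    ok = gwas[(~gwas["flagged"]) & (gwas["p_value"] < p_threshold)]
    freq_coded = panel.coded_allele_frequency()
    rows = []
    for snp, row in ok.iterrows():
        coded_is_risk = row["beta"] > 0
        rows.append({
            "snp_id": snp,
            "risk_allele": "coded" if coded_is_risk else "other",
            "weight": abs(float(row["beta"])),
            "p_value": float(row["p_value"]),
            "risk_allele_freq": float(freq_coded[snp] if coded_is_risk
                                      else 1.0 - freq_coded[snp]),
        })
    return pd.DataFrame(rows, columns=["snp_id", "risk_allele", "weight",
                                       "p_value", "risk_allele_freq"]
                        ).set_index("snp_id")


def compute_grs(panel: GenotypePanel, weights: pd.DataFrame) -> pd.Series:
    """Per-sample weighted risk-allele count.

    Missing genotypes contribute ``2 * risk_allele_freq * weight`` (mean
    imputation).  Raises if a weighted SNP is absent from the panel.
    """
    missing_snps = [s for s in weights.index if s not in panel.genotypes.columns]
    if missing_snps:
        raise ValueError(f"weights refer to SNPs absent from the panel: "
                         f"{missing_snps[:5]}")
    grs = pd.Series(0.0, index=panel.genotypes.index)
    for snp, row in weights.iterrows():
        g = panel.genotypes[snp].astype(float)
        if row["risk_allele"] == "other":
            g = 2.0 - g
        g = g.fillna(2.0 * row["risk_allele_freq"])
        grs = grs + g * row["weight"]
    return grs


def split_by_grs(grs: pd.Series) -> pd.Series:
    """Median split into "low"/"high"; ties at the median go to "low"."""
    if len(grs) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(grs.median())
    labels = pd.Series(np.where(grs > med, "high", "low"), index=grs.index)
    if (labels == "high").sum() == 0:
        import warnings
        warnings.warn("all GRS values tie at the median; 'high' group is empty")
    return labels
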