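"""Synthetic two-set case-control metabolomics studies with known ground truth.

The generator emulates the design of a nested case-control serum metabolomics
study of bladder cancer in middle-aged men: two independently recruited sets
(35 cases vs. 35 matched controls and 31 vs. 31), ~250 identified metabolites
among ~2610 LC-MS features, and a genome-wide SNP panel from which a genetic
risk score is built.  Everything the downstream pipeline is supposed to
recover is planted explicitly and returned as :class:`SyntheticTruth`:

* a sparse positive-definite precision matrix over a block of "network"
  metabolites — the dependency structure a Gaussian graphical model should
  recover from partial correlations;
* a subset of those network metabolites designated as biomarkers, whose
  log-abundance is shifted in cases by a configurable standardized effect in
  BOTH sets — the signal the replicated VIP > 1 filter should find;
* a set of risk SNPs with a common per-allele log-odds effect driving a
  logistic disease model — the weights a GWAS + genetic risk score should
  estimate.

Abundances are log-normal: the latent scale is Gaussian so that the pipeline's
log transform restores the Gaussian assumption behind the graphical model.
Case/control status is drawn from the SNP-driven logistic model over a large
genotyped pool, and study subjects are then sampled to hit the exact group
sizes, which keeps genetic risk-score recovery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import FeatureTable, GenotypePanel

SUPER_CLASSES = (
    "Organic acids and derivatives",
    "Organoheterocyclic compounds",
    "Benzenoids",
    "Organic oxygen compounds",
    "Fatty Acyls",
    "Polyketides",
    "Lipids and lipid-like molecules",
    "Organic nitrogen compounds",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated study: two male case-control sets of
    35+35 and 31+31, 2610 detected LC-MS features of which 250 are identified
    metabolites, a 23-metabolite network block containing 5 planted
    biomarkers, and a SNP panel with 92 risk SNPs feeding a weighted genetic
    risk score.
    """

    n_cases_set1: int = 35
    n_controls_set1: int = 35
    n_cases_set2: int = 31
    n_controls_set2: int = 31
    n_features: int = 2610
    n_identified: int = 250
    n_network: int = 23
    n_biomarkers: int = 5
    effect_size: float = 1.5
    precision_matrix_density: float = 0.08
    pcor_strength: float = 0.4
    n_snps: int = 500
    n_risk_snps: int = 92
    risk_allele_freqs: np.ndarray | None = None
    snp_effect_logodds: float = 0.25
    n_gwas_pool: int = 2000
    genotype_missing_rate: float = 0.01
    qc_detect_prob_background: float = 0.5
    qc_detect_prob_identified: float = 0.995
    n_qc_injections: int = 14
    qc_replicate_sigma_log: float = 0.1
    n_qc_replicates: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_biomarkers > self.n_network:
            raise ValueError("n_biomarkers must not exceed n_network")
        if self.n_network > self.n_identified or self.n_identified > self.n_features:
            raise ValueError("need n_network <= n_identified <= n_features")
        if self.n_risk_snps > self.n_snps:
            raise ValueError("n_risk_snps must not exceed n_snps")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.pcor_strength < 1.0):
            raise ValueError("pcor_strength must lie in [0, 1)")
        if not (0.0 <= self.precision_matrix_density < 1.0):
            raise ValueError("precision_matrix_density must lie in [0, 1)")
        if self.risk_allele_freqs is not None:
            f = np.asarray(self.risk_allele_freqs, dtype=float)
            if f.shape != (self.n_snps,):
                raise ValueError("risk_allele_freqs must have length n_snps")
            if np.any(f <= 0.05) or np.any(f >= 0.95):
                raise ValueError("risk allele frequencies must lie in (0.05, 0.95)")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["risk_allele_freqs"] is not None:
            d["risk_allele_freqs"] = list(map(float, d["risk_allele_freqs"]))
        return d


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_study`."""

    biomarker_indices: list[int]
    network_indices: list[int]
    true_precision: np.ndarray
    true_edges: set[tuple[int, int]]
    risk_snp_indices: list[int]
    true_snp_weights: np.ndarray
    disease_linear_predictor: pd.Series = field(default=None)  # per study sample

    @property
    def biomarker_ids(self) -> list[str]:
        return [_feature_id(i) for i in self.biomarker_indices]

    @property
    def network_ids(self) -> list[str]:
        return [_feature_id(i) for i in self.network_indices]

    @property
    def risk_snp_ids(self) -> list[str]:
        return [_snp_id(i) for i in self.risk_snp_indices]

    def true_grs_weights(self, panel) -> pd.DataFrame:
        """Risk-SNP weight table in the layout ``compute_grs`` expects,
        using the planted (not estimated) log-odds weights."""
        freq = panel.coded_allele_frequency()
        return pd.DataFrame(
            {"snp_id": self.risk_snp_ids,
             "risk_allele": "coded",
             "weight": self.true_snp_weights,
             "p_value": 0.0,
             "risk_allele_freq": [float(freq[s]) for s in self.risk_snp_ids]}
        ).set_index("snp_id")

    def implied_partial_correlations(self) -> np.ndarray:
        """Partial correlations implied by the planted precision matrix."""
        omega = self.true_precision
        d = np.sqrt(np.diag(omega))
        pcor = -omega / np.outer(d, d)
        np.fill_diagonal(pcor, 1.0)
        return pcor

    def write(self, path: str | Path) -> None:
        payload = {
            "biomarker_indices": self.biomarker_indices,
            "network_indices": self.network_indices,
            "true_precision": self.true_precision.tolist(),
            "true_edges": sorted(map(list, self.true_edges)),
            "risk_snp_indices": self.risk_snp_indices,
            "true_snp_weights": self.true_snp_weights.tolist(),
            "disease_linear_predictor": None
            if self.disease_linear_predictor is None
            else self.disease_linear_predictor.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        lp = d["disease_linear_predictor"]
        return cls(
            biomarker_indices=list(d["biomarker_indices"]),
            network_indices=list(d["network_indices"]),
            true_precision=np.asarray(d["true_precision"], dtype=float),
            true_edges={tuple(e) for e in d["true_edges"]},
            risk_snp_indices=list(d["risk_snp_indices"]),
            true_snp_weights=np.asarray(d["true_snp_weights"], dtype=float),
            disease_linear_predictor=None if lp is None else pd.Series(lp),
        )


def _feature_id(i: int) -> str:
    return f"F{i + 1:05d}"


def _snp_id(i: int) -> str:
    return f"rs{900000 + i}"


def make_precision_matrix(p: int, density: float, strength: float,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sparse symmetric positive-definite precision matrix with planted edges.

    Each off-diagonal pair is independently an edge with probability
    ``density``; edges receive entry ``-strength`` times a random sign on a
    unit diagonal, so the implied partial correlation
    ``-omega_ij / sqrt(omega_ii * omega_jj)`` has magnitude ``strength``
    (up to a uniform diagonal inflation applied only if needed to restore
    positive definiteness).

    Parameters
    ----------
    p : number of variables (>= 2)
    density : edge probability in [0, 1)
    strength : target |partial correlation| in [0, 1)
    seed : integer seed or a ``numpy.random.Generator``
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not (0.0 <= density < 1.0):
        raise ValueError("density must lie in [0, 1)")
    if not (0.0 <= strength < 1.0):
        raise ValueError("strength must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    omega = np.eye(p)
    iu = np.triu_indices(p, k=1)
    edge_mask = rng.random(len(iu[0])) < density
    signs = rng.choice((-1.0, 1.0), size=len(iu[0]))
    vals = np.where(edge_mask, -strength * signs, 0.0)
    omega[iu] = vals
    omega = omega + omega.T - np.eye(p) * 0.0
    np.fill_diagonal(omega, 1.0)

    # uniform diagonal inflation if the random support broke positive
    # definiteness; leaves the sparsity pattern (and hence the edge set) intact
    min_eig = np.linalg.eigvalsh(omega).min()
    if min_eig < 1e-3:
        omega[np.diag_indices(p)] += (1e-3 - min_eig)
    assert np.linalg.eigvalsh(omega).min() > 0, "precision matrix not positive definite"
    return omega


def edges_of(precision: np.ndarray, tol: float = 1e-12) -> set[tuple[int, int]]:
    """Unordered index pairs forming the off-diagonal support of a precision matrix."""
    p = precision.shape[0]
    return {(i, j) for i in range(p) for j in range(i + 1, p)
            if abs(precision[i, j]) > tol}


def generate_study(config: SimulationConfig
                   ) -> tuple[FeatureTable, FeatureTable, GenotypePanel, SyntheticTruth]:
    """Generate the full synthetic study: two feature tables, genotypes, truth.

    Returns ``(set1, set2, panel, truth)``.  The genotype panel contains the
    study subjects of both sets plus ``n_gwas_pool`` additional genotyped
    subjects (cohort "pool") whose case status came from the same logistic
    disease model; the pool is what gives a GWAS enough power to estimate the
    risk-SNP weights, mirroring a risk score trained on a full cohort and then
    applied to the nested sets.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    (ss_layout, ss_geno, ss_disease, ss_meta1, ss_meta2, ss_qc, ss_demo
     ) = [np.random.default_rng(s) for s in root.spawn(7)]

    # ---------------------------------------------------------------- layout
    perm = ss_layout.permutation(cfg.n_features)
    identified_idx = np.sort(perm[: cfg.n_identified])
    net_pos = np.sort(ss_layout.permutation(cfg.n_identified)[: cfg.n_network])
    network_idx = identified_idx[net_pos]
    bio_pos = np.sort(ss_layout.permutation(cfg.n_network)[: cfg.n_biomarkers])
    biomarker_idx = network_idx[bio_pos]

    omega = make_precision_matrix(cfg.n_network, cfg.precision_matrix_density,
                                  cfg.pcor_strength, ss_layout)
    sigma_net = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma_net)

    # -------------------------------------------------------------- genotypes
    if cfg.risk_allele_freqs is None:
        freqs = ss_geno.uniform(0.10, 0.90, size=cfg.n_snps)
    else:
        freqs = np.asarray(cfg.risk_allele_freqs, dtype=float)
    n_cases_needed = cfg.n_cases_set1 + cfg.n_cases_set2
    n_controls_needed = cfg.n_controls_set1 + cfg.n_controls_set2
    n_total = n_cases_needed + n_controls_needed + cfg.n_gwas_pool

    # oversample so exact case/control counts are reachable w.h.p.
    n_draw = int(2.5 * n_total) + 200
    G = ss_geno.binomial(2, freqs, size=(n_draw, cfg.n_snps)).astype(float)

    risk_idx = np.sort(ss_geno.permutation(cfg.n_snps)[: cfg.n_risk_snps])
    weights = np.full(cfg.n_risk_snps, cfg.snp_effect_logodds)
    lp = G[:, risk_idx] @ weights
    lp_centered = lp - lp.mean()
    status = (ss_disease.random(n_draw) < expit(lp_centered)).astype(int)

    case_rows = np.flatnonzero(status == 1)
    control_rows = np.flatnonzero(status == 0)
    if len(case_rows) < n_cases_needed or len(control_rows) < n_controls_needed:
        raise ValueError(
            "infeasible config: disease model produced too few cases or controls "
            f"({len(case_rows)} cases, {len(control_rows)} controls available)")

    study_cases = case_rows[:n_cases_needed]
    study_controls = control_rows[:n_controls_needed]
    pool_rows = np.setdiff1d(np.arange(n_draw),
                             np.concatenate([study_cases, study_controls]))
    pool_rows = pool_rows[: cfg.n_gwas_pool]

    order = np.concatenate([study_cases, study_controls, pool_rows])
    G = G[order]
    lp_centered = lp_centered[order]
    status = status[order]
    n_subjects = len(order)

    # cohort / set / group assignment in the reordered frame
    sets = np.array(["pool"] * n_subjects, dtype=object)
    groups = np.where(status == 1, "case", "control").astype(object)
    sets[: cfg.n_cases_set1] = "set1"
    sets[cfg.n_cases_set1: n_cases_needed] = "set2"
    sets[n_cases_needed: n_cases_needed + cfg.n_controls_set1] = "set1"
    sets[n_cases_needed + cfg.n_controls_set1:
         n_cases_needed + n_controls_needed] = "set2"

    sample_ids = [f"S{i + 1:05d}" for i in range(n_subjects)]

    # sprinkle missing genotype calls
    if cfg.genotype_missing_rate > 0:
        miss = ss_geno.random(G.shape) < cfg.genotype_missing_rate
        G[miss] = np.nan

    ages = np.clip(ss_demo.normal(52, 8, size=n_subjects)
                   + 2.0 * (status == 1), 35, 69).round(1)
    draw_dates = pd.to_datetime("2005-01-01") + pd.to_timedelta(
        ss_demo.integers(0, 365 * 8, size=n_subjects), unit="D")

    gsamples = pd.DataFrame(
        {"group": groups, "age": ages, "cohort": sets,
         "draw_date": draw_dates.strftime("%Y-%m-%d")},
        index=pd.Index(sample_ids, name="sample_id"))
    panel = GenotypePanel(
        genotypes=pd.DataFrame(G, index=gsamples.index,
                               columns=[_snp_id(j) for j in range(cfg.n_snps)]),
        samples=gsamples)

    # ---------------------------------------------------------- feature meta
    feature_ids = [_feature_id(j) for j in range(cfg.n_features)]
    identified_mask = np.zeros(cfg.n_features, dtype=bool)
    identified_mask[identified_idx] = True
    super_class = np.array([None] * cfg.n_features, dtype=object)
    super_class[identified_idx] = ss_layout.choice(SUPER_CLASSES,
                                                   size=cfg.n_identified)
    mz = np.round(ss_layout.uniform(80, 1000, size=cfg.n_features), 3)
    hmdb = np.array([None] * cfg.n_features, dtype=object)
    hmdb[identified_idx] = [f"HMDB{7000000 + j:07d}" for j in identified_idx]
    formula = np.array([None] * cfg.n_features, dtype=object)
    formula[identified_idx] = [f"C{ss_layout.integers(2, 30)}H{ss_layout.integers(4, 60)}NO{ss_layout.integers(1, 8)}"
                               for _ in identified_idx]

    det_prob = np.where(identified_mask, cfg.qc_detect_prob_identified,
                        cfg.qc_detect_prob_background)
    qc_detect = ss_qc.binomial(cfg.n_qc_injections, det_prob) / cfg.n_qc_injections

    base_log = ss_layout.uniform(np.log(1e4), np.log(1e6), size=cfg.n_features)
    features = pd.DataFrame(
        {"hmdb_like_id": hmdb, "mz": mz, "formula": formula,
         "super_class": super_class, "identified": identified_mask,
         "qc_detection": qc_detect},
        index=pd.Index(feature_ids, name="feature_id"))

    qc_reps = pd.DataFrame(
        np.exp(base_log + ss_qc.normal(0.0, cfg.qc_replicate_sigma_log,
                                       size=(cfg.n_qc_replicates, cfg.n_features))),
        index=pd.Index([f"QC{r + 1}" for r in range(cfg.n_qc_replicates)],
                       name="replicate_id"),
        columns=features.index)

    # ---------------------------------------------------------- abundances
    def _make_set(which: str, rng: np.random.Generator) -> FeatureTable:
        mask = sets == which
        ids = [s for s, m in zip(sample_ids, mask) if m]
        n = int(mask.sum())
        is_case = (groups[mask] == "case")

        latent = rng.standard_normal((n, cfg.n_features))
        latent[:, network_idx] = rng.standard_normal((n, cfg.n_network)) @ chol.T
        shift = np.zeros((n, cfg.n_features))
        sd_bio = np.sqrt(np.diag(sigma_net))[bio_pos]
        shift[np.ix_(is_case, biomarker_idx)] = cfg.effect_size * sd_bio
        log_ab = base_log + latent + shift
        abundance = pd.DataFrame(np.exp(log_ab), index=pd.Index(ids, name="sample_id"),
                                 columns=features.index)
        meta = gsamples.loc[ids, ["group", "age", "draw_date"]].copy()
        meta.insert(0, "set", which)
        meta = meta[["set", "group", "age", "draw_date"]]
        return FeatureTable(abundance=abundance, samples=meta, features=features,
                            qc_replicates=qc_reps)

    set1 = _make_set("set1", ss_meta1)
    set2 = _make_set("set2", ss_meta2)

    study_ids = list(set1.samples.index) + list(set2.samples.index)
    truth = SyntheticTruth(
        biomarker_indices=[int(i) for i in biomarker_idx],
        network_indices=[int(i) for i in network_idx],
        true_precision=omega,
        true_edges=edges_of(omega),
        risk_snp_indices=[int(i) for i in risk_idx],
        true_snp_weights=weights,
        disease_linear_predictor=pd.Series(lp_centered, index=sample_ids).loc[study_ids],
    )
    return set1, set2, panel, truth
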