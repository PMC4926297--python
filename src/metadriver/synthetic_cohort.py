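"""Synthetic multi-cancer cohorts with known planted structure.

Every downstream stage of the pipeline is exercised against cohorts whose
ground truth is known exactly:

* a latent per-sample hypoxia level ``h ~ Uniform(0, 1)``;
* segmental copy-number baselines per chromosome (3-8 segments, log2 ratios
  ``Normal(0, 0.05)``), on top of which each planted driver receives a focal
  gain (log2 ratio ``Uniform(0.3, 1.2)``) in a Bernoulli-selected sample
  subset whose expected size is ``driver_gain_fraction``; for
  hypoxia-coupled drivers the per-sample gain probability is tilted by
  ``hypoxia_gain_slope`` around the latent-hypoxia mean, so the marginal
  gain fraction is preserved while gains co-vary with hypoxia;
* tumour expression = gene baseline + over-expression shift (drivers only)
  + a coupling multiple of the gene's standardised log2 ratio (drivers
  only; the multiplier is solved numerically so the expression-dosage
  Spearman correlation hits ``driver_coupling`` at the generator's noise
  level) + ``hypoxia_effect * h`` (signature genes and hypoxia-coupled
  drivers) + Gaussian noise; normal-tissue expression is baseline + noise;
* sparse somatic mutations (Bernoulli per gene and sample);
* survival times from an exponential model whose log hazard is a linear
  function of standardised planted-prognostic-gene expression (alternating
  coefficient signs), with independent exponential censoring.

The gene universe (ids, annotation, planted gene sets) depends only on the
base seed, so cohorts of one pan-cancer simulation share genes and
annotation while their per-sample draws differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .io_core import CohortBundle
from .scna import call_scna

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice_site")


@dataclass
class SimulationParams:
    """Generator settings; the defaults are the reference study conditions."""

    n_cancers: int = 3
    n_tumour: int = 200
    n_normal: int = 50
    n_genes: int = 2000
    n_chromosomes: int = 10
    n_planted_drivers: int = 20
    driver_coupling: float = 0.6  # target expression-dosage Spearman rho
    driver_gain_fraction: float = 0.5
    overexpression_shift: float = 1.0  # log2 units
    n_signature_genes: int = 30
    hypoxia_effect: float = 1.0  # log2 units per unit latent hypoxia
    n_hypoxia_coupled_drivers: int = 10
    hypoxia_gain_slope: float = 0.5  # gain-probability tilt per unit latent hypoxia
    n_prognostic_genes: int = 3
    prognostic_beta: float = 0.8  # log hazard per standardised log2 unit
    baseline_hazard: float = 0.1  # events per year
    censor_rate: float = 0.05  # censorings per year
    mutation_rate: float = 0.01  # per gene per sample
    noise_sd: float = 1.0  # log2 units
    metabolic_fraction: float = 0.25
    expression_baseline_mean: float = 7.0
    expression_baseline_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_drivers + self.n_signature_genes + self.n_prognostic_genes > self.n_genes:
            raise ValueError("more planted genes than genes in the universe")
        if self.n_hypoxia_coupled_drivers > self.n_planted_drivers:
            raise ValueError("hypoxia-coupled drivers must be a subset of planted drivers")
        if not 0 <= self.driver_coupling <= 1:
            raise ValueError("driver_coupling must lie in [0, 1]")
        if not 0 < self.driver_gain_fraction <= 1:
            raise ValueError("driver_gain_fraction must lie in (0, 1]")
        for name in ("baseline_hazard", "censor_rate", "mutation_rate", "noise_sd",
                     "hypoxia_gain_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")


@dataclass
class GroundTruth:
    planted_drivers: set[str]
    hypoxia_coupled: set[str]
    prognostic: dict[str, float]  # gene -> signed log-hazard coefficient
    latent_hypoxia: pd.Series
    signature_genes: set[str]
    metabolic_genes: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# gene universe

GENE_LENGTH = 10_000
GENE_SPACING = 100_000
BAND_BLOCK = 50  # genes per cytoband


def gene_universe(params: SimulationParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Shared annotation and planted gene sets, deterministic in the base seed.

    Genes are uniformly spaced across ``n_chromosomes``; the first half of
    each chromosome is the p arm; cytobands cover blocks of 50 genes.
    Planted drivers, signature genes and prognostic genes are disjoint;
    the metabolic flag covers all planted drivers plus a random fill up to
    ``metabolic_fraction`` of the universe.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    width = max(4, len(str(params.n_genes - 1)))
    genes = np.array([f"G{i:0{width}d}" for i in range(params.n_genes)])
    per_chrom = math.ceil(params.n_genes / params.n_chromosomes)
    chrom, start, end, band = [], [], [], []
    for i in range(params.n_genes):
        c, j = divmod(i, per_chrom)
        chrom.append(f"chr{c + 1}")
        s = 1 + j * GENE_SPACING
        start.append(s)
        end.append(s + GENE_LENGTH - 1)
        arm = "p" if j < per_chrom / 2 else "q"
        j_arm = j if arm == "p" else j - math.ceil(per_chrom / 2)
        band.append(f"{arm}{j_arm // BAND_BLOCK + 1}")
    order = rng.permutation(params.n_genes)
    n_drv, n_sig, n_prog = (
        params.n_planted_drivers,
        params.n_signature_genes,
        params.n_prognostic_genes,
    )
    drivers = set(genes[order[:n_drv]])
    coupled = set(genes[order[: params.n_hypoxia_coupled_drivers]])
    signature = set(genes[order[n_drv : n_drv + n_sig]])
    prog_genes = genes[order[n_drv + n_sig : n_drv + n_sig + n_prog]]
    prognostic = {
        g: params.prognostic_beta * (1.0 if k % 2 == 0 else -1.0)
        for k, g in enumerate(prog_genes)
    }
    n_metabolic = max(int(round(params.metabolic_fraction * params.n_genes)), n_drv)
    metabolic = set(drivers)
    for g in genes[order]:
        if len(metabolic) >= n_metabolic:
            break
        if g not in signature and g not in prognostic:
            metabolic.add(g)
    ann = pd.DataFrame(
        {
            "gene_id": genes,
            "chromosome": chrom,
            "start": start,
            "end": end,
            "cytoband": band,
            "is_metabolic": [g in metabolic for g in genes],
        }
    )
    truth = GroundTruth(
        planted_drivers=drivers,
        hypoxia_coupled=coupled,
        prognostic=prognostic,
        latent_hypoxia=pd.Series(dtype=float),
        signature_genes=signature,
        metabolic_genes=metabolic,
    )
    return ann, truth


# ---------------------------------------------------------------------------
# coupling calibration


@lru_cache(maxsize=64)
def solve_coupling(target_rho: float, noise_sd: float, gain_fraction: float) -> float:
    """Coupling multiplier producing the target expression-dosage Spearman rho.

    Solved by bisection on a large fixed calibration sample drawn from the
    generator's own copy-number mixture (focal gains at ``gain_fraction``
    over the segmental baseline) at the generator's noise level.
    """
    if target_rho <= 0:
        return 0.0
    from scipy.stats import spearmanr

    rng = np.random.default_rng(987_654_321)
    n = 20_000
    gained = rng.random(n) < gain_fraction
    cn = np.where(gained, rng.uniform(0.3, 1.2, n), rng.normal(0, 0.05, n))
    z = (cn - cn.mean()) / cn.std()
    eps = rng.normal(0, 1, n)

    def rho(c: float) -> float:
        return float(spearmanr(c * z + noise_sd * eps, cn).statistic)

    lo, hi = 0.0, max(noise_sd, 1e-6)
    while rho(hi) < target_rho:
        hi *= 2
        if hi > 1e4:
            raise ValueError(f"target rho {target_rho} unreachable at this noise level")
    for _ in range(40):
        mid = (lo + hi) / 2
        if rho(mid) < target_rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(params: SimulationParams, cancer_index: int = 0) -> tuple[CohortBundle, GroundTruth]:
    """One cohort with planted drivers, hypoxia axis, mutations and survival."""
    params.validate()
    ann, truth = gene_universe(params)
    genes = ann["gene_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng((params.seed + cancer_index) % (2**31 - 1))
    n_t, n_n, n_g = params.n_tumour, params.n_normal, params.n_genes
    tumour_ids = [f"C{cancer_index}T{j:04d}" for j in range(n_t)]
    normal_ids = [f"C{cancer_index}N{j:04d}" for j in range(n_n)]

    h = rng.uniform(0.0, 1.0, n_t)

    # segmental copy-number baseline: 3-8 segments per chromosome and sample
    cn = np.empty((n_g, n_t))
    for chrom, grp in ann.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        m = idx.size
        for s in range(n_t):
            n_seg = int(rng.integers(3, 9))
            n_seg = min(n_seg, m)
            cuts = np.sort(rng.choice(np.arange(1, m), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], dtype=int)
            bounds = np.concatenate([[0], cuts, [m]])
            values = rng.normal(0.0, 0.05, n_seg)
            for k in range(n_seg):
                cn[idx[bounds[k] : bounds[k + 1]], s] = values[k]

    # focal gains for planted drivers
    for g in sorted(truth.planted_drivers):
        i = gene_pos[g]
        p = np.full(n_t, params.driver_gain_fraction)
        if g in truth.hypoxia_coupled:
            p = np.clip(p + params.hypoxia_gain_slope * (h - 0.5), 0.0, 1.0)
        gained = rng.random(n_t) < p
        cn[i, gained] = rng.uniform(0.3, 1.2, int(gained.sum()))

    baseline = rng.normal(params.expression_baseline_mean, params.expression_baseline_sd, n_g)
    c = solve_coupling(params.driver_coupling, params.noise_sd, params.driver_gain_fraction)

    expr = baseline[:, None] + rng.normal(0.0, params.noise_sd, (n_g, n_t))
    for g in sorted(truth.planted_drivers):
        i = gene_pos[g]
        expr[i] += params.overexpression_shift
        sd = cn[i].std()
        if c > 0 and sd > 0:
            expr[i] += c * (cn[i] - cn[i].mean()) / sd
    for g in sorted(truth.signature_genes | truth.hypoxia_coupled):
        expr[gene_pos[g]] += params.hypoxia_effect * h

    normal = baseline[:, None] + rng.normal(0.0, params.noise_sd, (n_g, n_n))

    # sparse somatic mutations
    mutated = rng.random((n_g, n_t)) < params.mutation_rate
    gi, si = np.nonzero(mutated)
    mutations = pd.DataFrame(
        {
            "gene_id": genes[gi],
            "sample_id": [tumour_ids[j] for j in si],
            "variant_class": rng.choice(VARIANT_CLASSES, size=gi.size),
        }
    )

    # survival: exponential hazard on standardised prognostic expression
    log_hr = np.zeros(n_t)
    for g, beta in sorted(truth.prognostic.items()):
        row = expr[gene_pos[g]]
        log_hr += beta * (row - row.mean()) / row.std()
    rate = params.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)
    if params.censor_rate > 0:
        censor_time = rng.exponential(1.0 / params.censor_rate, n_t)
    else:
        censor_time = np.full(n_t, np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    clinical = pd.DataFrame(
        {
            "sample_id": tumour_ids,
            "time_years": time,
            "event": event,
            "age": rng.normal(58.0, 10.0, n_t),
            "stage": rng.choice([1, 2, 3, 4], size=n_t, p=[0.3, 0.4, 0.2, 0.1]),
            "subtype": rng.choice(["A", "B"], size=n_t),
        }
    )

    gene_index = pd.Index(genes, name="gene_id")
    cn_df = pd.DataFrame(cn, index=gene_index, columns=tumour_ids)
    bundle = CohortBundle(
        name=f"cancer_{cancer_index}",
        tumour_expr=pd.DataFrame(expr, index=gene_index, columns=tumour_ids),
        normal_expr=pd.DataFrame(normal, index=gene_index, columns=normal_ids),
        cn_log2=cn_df,
        scna_calls=call_scna(cn_df),
        mutations=mutations,
        clinical=clinical,
        annotation=ann,
        hypoxia_signature=sorted(truth.signature_genes),
    )
    truth.latent_hypoxia = pd.Series(h, index=tumour_ids, name="latent_hypoxia")
    return bundle, truth


def simulate_pan_cancer(params: SimulationParams) -> list[tuple[CohortBundle, GroundTruth]]:
    """Several cohorts sharing the gene universe; per-cancer seeds are seed + index."""
    return [simulate_cohort(params, i) for i in range(params.n_cancers)]
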