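"""Synthetic oocyte-maturation data generator.

Emulates the statistical structure the analysis pipeline assumes:

* a latent NSN->SN progression ``t`` in [0, 1] per GV oocyte that drives
  SN-featured genes (2-fold by default) and non-monotone trajectory genes
  (piecewise-linear in ``t`` with a breakpoint at 0.5);
* global RNA degradation from GV to MII (default: only 25% of the
  transcriptome mass is retained), with per-gene retention factors ``d_i``;
* ERCC-style spike-ins whose expectations are invariant to stage, dilution
  fraction and degradation;
* residual rRNA coverage over the 13,403-base primary transcript with a
  stage-linked 5'-ETS component;
* PCR-duplicated reads carrying N8 UMIs.

Counts are negative binomial with mean ``m`` and variance ``m + alpha*m^2``;
``alpha = 0`` degenerates to Poisson.  Every generator takes an explicit
seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import ETS5_END, RRNA_TRANSCRIPT_LENGTH, CountMatrix, classify_features

TRAJECTORY_CLASSES = ("up-up", "up-dn", "dn-up", "dn-dn", "flat")

#: Mature-rRNA segments of the primary transcript (transcript coordinates,
#: 1-based inclusive): 18S, 5.8S, 28S.  Baseline residual coverage in poly(A)
#: libraries concentrates here; the 5'-ETS signal (positions 1..4007) rides
#: on top with sample-specific amplitude.
MATURE_SEGMENTS = ((4_008, 5_877), (6_877, 7_033), (8_123, 12_852))


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions for desk-scale runs."""

    n_genes: int = 2_000
    n_gv: int = 12
    n_mii: int = 12
    n_spikes: int = 92
    global_retention: float = 0.25
    sn_fold: float = 2.0
    n_sn_featured: int = 150
    n_nsn_featured: int = 150
    #: fraction of genes per non-flat trajectory class (up-up, up-dn, dn-up, dn-dn)
    trajectory_fractions: dict = field(
        default_factory=lambda: {
            "up-up": 0.05,
            "up-dn": 0.05,
            "dn-up": 0.05,
            "dn-dn": 0.05,
        }
    )
    trajectory_fold: float = 2.0  # per-phase fold for trajectory genes
    flat_fraction: float = 0.15  # retention-stable genes (constGene truth)
    dispersion: float = 0.05
    mu_log_mean: float = 5.0  # ln-scale baseline expression
    mu_log_sd: float = 1.0
    size_factor_sd: float = 0.3  # ln-scale spread of true size factors
    spike_log_mean: float = 4.0  # ln-scale spike concentration spread
    spike_log_sd: float = 1.0
    spike_capture: float = 1.0  # kappa: counts per concentration unit
    ets_intercept: float = 0.005  # a in e_j = a + b*t_j + noise
    ets_slope: float = 0.010  # b
    ets_noise_sd: float = 0.001
    stage_distribution: str = "uniform"  # t_j distribution over [0, 1]
    gene_length: int = 1_000  # position space for simulated reads
    umi_length: int = 8


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated cohort."""

    config: SimConfig
    seed: int
    mu: pd.Series  # baseline GV expectation per gene
    retention: pd.Series  # d_i: MII expectation = d_i * mu_i
    trajectory_class: pd.Series  # per-gene class incl. 'flat'
    sn_featured: list
    nsn_featured: list
    stage_score: pd.Series  # t_j per GV sample
    size_factor: pd.Series  # s*_j per sample (GV + MII)
    spike_concentration: pd.Series
    ets_amplitude: pd.Series  # e_j per GV sample
    dispersion: float

    @property
    def flat_genes(self) -> list:
        return list(self.retention.index[self.trajectory_is_flat_retention()])

    def trajectory_is_flat_retention(self) -> np.ndarray:
        lo, hi = 1.0 / 1.5, 1.5
        d = self.retention.to_numpy()
        return (d > lo) & (d < hi)


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned read with its N8 UMI."""

    sample_id: str
    gene_id: str
    position: int
    strand: str
    umi: str


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean m, var m + alpha m^2); alpha = 0 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def simulate_truth(config: SimConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Draw the latent ground truth for a synthetic oocyte cohort.

    Deterministic for a fixed seed.  Baseline expectations are log-normal;
    SN-featured genes scale linearly in ``t`` to ``sn_fold`` at ``t = 1``;
    trajectory genes are piecewise-linear in ``t`` with a breakpoint at 0.5.
    Per-gene retention factors are rescaled so the mass-weighted global
    retention matches ``config.global_retention`` exactly.
    """
    cfg = config or SimConfig()
    frac_sum = sum(cfg.trajectory_fractions.values())
    if frac_sum > 1 + 1e-12:
        raise ValueError(f"trajectory class fractions sum to {frac_sum} > 1")
    rng = np.random.default_rng(seed)

    genes = pd.Index([f"gene_{i:05d}" for i in range(cfg.n_genes)])
    mu = pd.Series(
        np.exp(rng.normal(cfg.mu_log_mean, cfg.mu_log_sd, cfg.n_genes)), index=genes
    )

    # trajectory classes for GV progression
    traj = pd.Series("flat", index=genes, dtype=object)
    pool = list(genes)
    rng.shuffle(pool)
    cursor = 0
    for cls in ("up-up", "up-dn", "dn-up", "dn-dn"):
        k = int(round(cfg.trajectory_fractions.get(cls, 0.0) * cfg.n_genes))
        traj.loc[pool[cursor : cursor + k]] = cls
        cursor += k
    # SN/NSN-featured genes drawn from the remaining (trajectory-flat) pool
    remaining = [g for g in pool[cursor:]]
    if cfg.n_sn_featured + cfg.n_nsn_featured > len(remaining):
        raise ValueError("not enough genes for SN/NSN feature sets")
    sn_featured = sorted(remaining[: cfg.n_sn_featured])
    nsn_featured = sorted(
        remaining[cfg.n_sn_featured : cfg.n_sn_featured + cfg.n_nsn_featured]
    )

    # retention: flat genes stay within (1/1.5, 1.5); the rest degrade and are
    # rescaled so that sum(d*mu)/sum(mu) == global_retention exactly
    n_flat = int(round(cfg.flat_fraction * cfg.n_genes))
    flat_idx = rng.choice(cfg.n_genes, size=n_flat, replace=False)
    is_flat = np.zeros(cfg.n_genes, dtype=bool)
    is_flat[flat_idx] = True
    log2_bound = np.log2(1.5)
    d = np.empty(cfg.n_genes)
    flat_draw = rng.normal(0.0, 0.2, n_flat)
    flat_draw = np.clip(flat_draw, -0.95 * log2_bound, 0.95 * log2_bound)
    d[is_flat] = 2.0**flat_draw
    d[~is_flat] = np.exp(rng.normal(np.log(0.15), 0.8, cfg.n_genes - n_flat))
    w = mu.to_numpy()
    target = cfg.global_retention * w.sum()
    flat_mass = (d[is_flat] * w[is_flat]).sum()
    if (~is_flat).any():
        if target <= flat_mass:
            raise ValueError(
                "flat genes alone exceed the configured global retention"
            )
        # scale non-flat genes to hit the target exactly, pinning any that
        # would land inside the flat window (the constGene truth set must be
        # exactly the flat class); iterate until the pinned set stabilizes
        lo, hi = 1.0 / 1.5, 1.5
        pinned = np.zeros(cfg.n_genes, dtype=bool)
        for _ in range(20):
            free = ~is_flat & ~pinned
            fixed_mass = flat_mass + (d[pinned] * w[pinned]).sum()
            free_mass = (d[free] * w[free]).sum()
            if free_mass <= 0 or target <= fixed_mass:
                raise ValueError("cannot satisfy global retention constraint")
            d[free] *= (target - fixed_mass) / free_mass
            strayed = free & (d > lo) & (d < hi)
            if not strayed.any():
                break
            d[strayed] = np.where(d[strayed] >= 1.0, hi * 1.05, lo * 0.95)
            pinned |= strayed
    elif abs(flat_mass - target) > 1e-6 * target:
        d[is_flat] *= target / flat_mass
    retention = pd.Series(d, index=genes)

    gv_ids = [f"GV_{j + 1:03d}" for j in range(cfg.n_gv)]
    mii_ids = [f"MII_{j + 1:03d}" for j in range(cfg.n_mii)]
    if cfg.stage_distribution == "uniform":
        t = rng.uniform(0.0, 1.0, cfg.n_gv)
    else:
        raise ValueError(f"unknown stage distribution {cfg.stage_distribution!r}")
    stage_score = pd.Series(t, index=gv_ids)

    size_factor = pd.Series(
        np.exp(rng.normal(0.0, cfg.size_factor_sd, cfg.n_gv + cfg.n_mii)),
        index=gv_ids + mii_ids,
    )
    spikes = pd.Index([f"ERCC-{i + 1:05d}" for i in range(cfg.n_spikes)])
    spike_concentration = pd.Series(
        np.exp(rng.normal(cfg.spike_log_mean, cfg.spike_log_sd, cfg.n_spikes)),
        index=spikes,
    )
    ets = cfg.ets_intercept + cfg.ets_slope * t + rng.normal(
        0.0, cfg.ets_noise_sd, cfg.n_gv
    )
    ets_amplitude = pd.Series(np.clip(ets, 0.0, None), index=gv_ids)

    return SyntheticTruth(
        config=cfg,
        seed=seed,
        mu=mu,
        retention=retention,
        trajectory_class=traj,
        sn_featured=sn_featured,
        nsn_featured=nsn_featured,
        stage_score=stage_score,
        size_factor=size_factor,
        spike_concentration=spike_concentration,
        ets_amplitude=ets_amplitude,
        dispersion=cfg.dispersion,
    )


def _trajectory_factor(cls: str, t: np.ndarray, fold: float) -> np.ndarray:
    """Piecewise-linear log2 profile in t, breakpoint 0.5, +/- log2(fold) per phase."""
    delta = np.log2(fold)
    sign1 = 1.0 if cls.startswith("up") else -1.0
    sign2 = 1.0 if cls.endswith("up") else -1.0
    phase1 = np.minimum(t, 0.5) / 0.5
    phase2 = np.maximum(t - 0.5, 0.0) / 0.5
    return 2.0 ** (sign1 * delta * phase1 + sign2 * delta * phase2)


def expected_gene_matrix(truth: SyntheticTruth) -> pd.DataFrame:
    """Stage/trajectory expectations q_ij (before size factors), genes x samples."""
    cfg = truth.config
    gv = list(truth.stage_score.index)
    mii = [s for s in truth.size_factor.index if s not in truth.stage_score.index]
    t = truth.stage_score.to_numpy()
    q = np.tile(truth.mu.to_numpy()[:, None], (1, len(gv) + len(mii))).astype(float)
    genes = truth.mu.index
    pos = {g: i for i, g in enumerate(genes)}
    ngv = len(gv)

    sn_rows = [pos[g] for g in truth.sn_featured]
    if sn_rows:
        q[np.ix_(sn_rows, range(ngv))] *= 1.0 + (cfg.sn_fold - 1.0) * t[None, :]
    nsn_rows = [pos[g] for g in truth.nsn_featured]
    if nsn_rows:
        q[np.ix_(nsn_rows, range(ngv))] *= 1.0 + (cfg.sn_fold - 1.0) * (
            1.0 - t[None, :]
        )
    for cls in ("up-up", "up-dn", "dn-up", "dn-dn"):
        rows = [pos[g] for g in genes[truth.trajectory_class == cls]]
        if rows:
            q[np.ix_(rows, range(ngv))] *= _trajectory_factor(
                cls, t, cfg.trajectory_fold
            )[None, :]
    if mii:
        q[:, ngv:] = truth.mu.to_numpy()[:, None] * truth.retention.to_numpy()[:, None]
    return pd.DataFrame(q, index=genes, columns=gv + mii)


def _spike_means(truth: SyntheticTruth) -> pd.Series:
    return truth.spike_concentration * truth.config.spike_capture


def _meta_frame(sample_ids, stages, dataset, library_type="polyA", material="single"):
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "stage": list(stages),
            "dataset": dataset,
            "library_type": library_type,
            "material": material,
        }
    )


def simulate_counts(
    truth: SyntheticTruth,
    seed: int | None = None,
    dataset: str = "synthetic",
    library_type: str = "polyA",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a gene+spike count matrix and its metadata from the truth.

    Counts are NB(mean = s*_j * q_ij, dispersion alpha); spike rows use
    mean = s*_j * concentration * kappa, identical across stages.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    q = expected_gene_matrix(truth)
    samples = list(q.columns)
    sf = truth.size_factor.loc[samples].to_numpy()
    gene_mean = q.to_numpy() * sf[None, :]
    spike_mean = np.tile(_spike_means(truth).to_numpy()[:, None], (1, len(samples)))
    spike_mean = spike_mean * sf[None, :]
    mean = np.vstack([gene_mean, spike_mean])
    counts = _nb_sample(rng, mean, truth.dispersion)
    index = list(q.index) + list(truth.spike_concentration.index)
    values = pd.DataFrame(counts, index=index, columns=samples)
    cm = CountMatrix(values, classify_features(values.index))
    stages = ["GV" if s in truth.stage_score.index else "MII" for s in samples]
    meta = _meta_frame(samples, stages, dataset, library_type)
    return cm, meta


def simulate_coverage(
    truth: SyntheticTruth,
    seed: int | None = None,
    depth: float = 1_000.0,
    noise_sd: float = 0.0,
) -> dict[str, np.ndarray]:
    """Per-GV-sample rRNA coverage over the 13,403-base primary transcript.

    Baseline coverage sits on the mature 18S/5.8S/28S segments; a 5'-ETS
    component uniform over positions 1..4007 is added with per-sample
    amplitude ``e_j`` relative to the mature mass.
    """
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    base = np.zeros(RRNA_TRANSCRIPT_LENGTH)
    for start, end in MATURE_SEGMENTS:
        base[start - 1 : end] = 1.0
    base /= base.sum()
    ets = np.zeros(RRNA_TRANSCRIPT_LENGTH)
    ets[:ETS5_END] = 1.0 / ETS5_END
    profiles: dict[str, np.ndarray] = {}
    for sample, e in truth.ets_amplitude.items():
        cov = depth * (base + e * ets)
        if noise_sd > 0:
            cov = np.clip(cov * (1.0 + rng.normal(0.0, noise_sd, cov.shape)), 0, None)
        profiles[sample] = cov
    return profiles


def simulate_reads(
    truth: SyntheticTruth,
    amplification: float,
    n_molecules: dict[str, int] | pd.Series,
    sample_id: str = "S1",
    seed: int | None = None,
    duplication: str = "poisson",
) -> list[ReadRecord]:
    """Emit PCR-duplicated UMI-tagged reads for one library.

    Each original molecule gets a distinct draw of (position, strand, UMI),
    UMIs uniform over the 4^8 space, and is emitted D times with
    D ~ 1 + Poisson(amplification - 1) (``duplication='poisson'``) or a
    fixed D = round(amplification) (``duplication='fixed'``).
    """
    if amplification < 1:
        raise ValueError("amplification must be >= 1")
    cfg = truth.config
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    alphabet = np.array(list("ACGT"))
    reads: list[ReadRecord] = []
    for gene_id, n_mol in pd.Series(n_molecules).items():
        n_mol = int(n_mol)
        if n_mol == 0:
            continue
        positions = rng.integers(1, cfg.gene_length + 1, n_mol)
        strands = np.where(rng.random(n_mol) < 0.5, "+", "-")
        umis = alphabet[rng.integers(0, 4, (n_mol, cfg.umi_length))]
        if duplication == "fixed":
            dups = np.full(n_mol, int(round(amplification)))
        elif duplication == "poisson":
            dups = 1 + rng.poisson(amplification - 1.0, n_mol)
        else:
            raise ValueError(f"unknown duplication mode {duplication!r}")
        for m in range(n_mol):
            rec = ReadRecord(
                sample_id=sample_id,
                gene_id=str(gene_id),
                position=int(positions[m]),
                strand=str(strands[m]),
                umi="".join(umis[m]),
            )
            reads.extend([rec] * int(dups[m]))
    return reads


def simulate_dilution_series(
    truth: SyntheticTruth,
    fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125),
    n_replicates: int = 3,
    seed: int | None = None,
    dataset: str = "dilution",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Fractional-oocyte series: gene expectations scale by the fraction,
    spike expectations do not (spikes are added after dilution)."""
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(truth.seed + 4 if seed is None else seed)
    mu = truth.mu.to_numpy()
    spike_mean = _spike_means(truth).to_numpy()
    cols, means = [], []
    for f in fractions:
        for r in range(n_replicates):
            cols.append(f"f{f:g}_r{r + 1}")
            means.append(np.concatenate([mu * f, spike_mean]))
    mean = np.column_stack(means)
    counts = _nb_sample(rng, mean, truth.dispersion)
    index = list(truth.mu.index) + list(truth.spike_concentration.index)
    values = pd.DataFrame(counts, index=index, columns=cols)
    cm = CountMatrix(values, classify_features(values.index))
    meta = _meta_frame(cols, ["GV"] * len(cols), dataset)
    meta["fraction"] = [f for f in fractions for _ in range(n_replicates)]
    return cm, meta


def reads_to_counts(reads: list[ReadRecord]) -> pd.DataFrame:
    """Collapse read records into a gene x sample count table."""
    if not reads:
        return pd.DataFrame()
    df = pd.DataFrame(
        {"gene_id": [r.gene_id for r in reads], "sample_id": [r.sample_id for r in reads]}
    )
    return (
        df.groupby(["gene_id", "sample_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
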