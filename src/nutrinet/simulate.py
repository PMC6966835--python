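"""Synthetic fasting-vs-fed transcriptome datasets with known ground truth.

The generator emulates the structure of a two-group skeletal-muscle
RNA-seq + small-RNA-seq experiment: 11 fasted vs 12 fed samples, three
biotypes with contrasting abundance and variability regimes (mRNAs
abundant with moderate biological coefficient of variation, miRNAs
intermediate-abundance and very stable, lincRNAs scarce and wildly
variable), planted differentially expressed and differentially dispersed
genes, regulator miRNAs that repress planted target mRNAs through shared
biological noise, matching 7mer-m8 seed sites in synthetic 3'-UTRs, and
phenotypic traits coupled to planted co-expression modules.

All downstream stages of the pipeline can therefore be exercised, and
their recovery of the planted truth quantified, without any sequencing
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .modules import module_eigengene
from .seeds import scan_sites, seed_site

BIOTYPES = ("mRNA", "miRNA", "lincRNA")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults mirror the emulated experiment: group sizes 11 and 12 (one
    fasted sample excluded), biotype BCVs of 0.53 (mRNA), 0.37 (miRNA)
    and 1.15 (lincRNA), and mean-abundance ordering mRNA > miRNA >
    lincRNA.  ``coupling_strength`` is the fraction of a target mRNA's
    biological log-variance driven by its regulator miRNA, so the planted
    regulator-target correlation approaches -sqrt(coupling_strength).
    """

    n_mrna: int = 500
    n_mirna: int = 60
    n_lincrna: int = 20
    n_samples_per_group: tuple[int, int] = (11, 12)
    baseline_log2cpm: tuple[float, float, float] = (6.0, 4.5, 1.5)
    baseline_sd: float = 2.0
    bcv: tuple[float, float, float] = (0.53, 0.37, 1.15)
    frac_de: float = 0.10
    de_log2fc_magnitude: float = 1.0
    frac_dd: float = 0.05
    dd_dispersion_fc: float = 4.0
    n_regulator_mirnas: int = 5
    targets_per_regulator: int = 10
    coupling_strength: float = 0.8
    utr_length: int = 500
    n_traits: int = 6
    trait_r2: float = 0.6
    n_modules: int = 3
    module_size: int = 50
    module_rho: float = 0.75
    mean_library_size: float = 1e6
    library_spread: float = 0.3
    group_labels: tuple[str, str] = ("fasted", "fed")
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_mirna", "n_lincrna", "n_regulator_mirnas",
                     "targets_per_regulator", "n_traits", "n_modules",
                     "module_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if any(n <= 0 for n in self.n_samples_per_group):
            raise ConfigurationError("group sizes must be positive")
        for name in ("frac_de", "frac_dd", "coupling_strength", "module_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.trait_r2 < 1.0:
            raise ConfigurationError("trait_r2 must lie in [0, 1)")
        if any(b < 0 for b in self.bcv):
            raise ConfigurationError("BCV values must be non-negative")
        if self.utr_length < 7:
            raise ConfigurationError("utr_length must be at least 7 bases")
        if self.dd_dispersion_fc <= 0:
            raise ConfigurationError("dd_dispersion_fc must be positive")


@dataclass
class GroundTruth:
    """Planted truth of one simulated dataset."""

    de_genes: dict = field(default_factory=dict)          # gene -> true log2FC
    dd_genes: dict = field(default_factory=dict)          # gene -> dispersion FC
    regulator_map: dict = field(default_factory=dict)     # miRNA -> set of mRNA targets
    planted_sites: list = field(default_factory=list)     # (mRNA, 1-based pos, miRNA)
    module_map: dict = field(default_factory=dict)        # gene -> planted block label
    trait_module_map: dict = field(default_factory=dict)  # trait -> block label
    mirna_sequences: dict = field(default_factory=dict)   # miRNA -> mature RNA seq
    utr_sequences: dict = field(default_factory=dict)     # mRNA -> DNA UTR
    baseline_log2cpm: dict = field(default_factory=dict)  # gene -> planted log2 CPM
    library_sizes: dict = field(default_factory=dict)     # sample -> nominal depth


def _gene_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    mr = [f"mRNA_{i:04d}" for i in range(1, config.n_mrna + 1)]
    mi = [f"miR_{i:03d}" for i in range(1, config.n_mirna + 1)]
    li = [f"linc_{i:03d}" for i in range(1, config.n_lincrna + 1)]
    return mr, mi, li


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw the count matrix and record the planted truth.

    Counts are gene-wise negative binomial (Gamma-Poisson) with biotype
    baseline means, group-shifted means for DE genes and group-shifted
    dispersions for DD genes; planted module members additionally share a
    per-module latent factor through a moment-matched log-normal
    biological component.  Library sizes vary log-uniformly by
    +/- ``library_spread`` around the mean.
    """
    rng = np.random.default_rng(config.seed)
    mr, mi, li = _gene_ids(config)
    genes = mr + mi + li
    biotype = pd.Series(
        ["mRNA"] * len(mr) + ["miRNA"] * len(mi) + ["lincRNA"] * len(li),
        index=genes, name="biotype",
    )
    n1, n2 = config.n_samples_per_group
    g1, g2 = config.group_labels
    samples = [f"{g1}_{i:02d}" for i in range(1, n1 + 1)]
    samples += [f"{g2}_{i:02d}" for i in range(1, n2 + 1)]
    group = pd.Series([g1] * n1 + [g2] * n2, index=samples, name="group")
    in_group2 = (group == g2).to_numpy()

    truth = GroundTruth()

    # --- carve disjoint planted gene sets out of the mRNA pool ---------
    free_mrna = list(mr)
    need = config.n_modules * config.module_size
    if need + config.n_regulator_mirnas * config.targets_per_regulator > len(free_mrna):
        raise ConfigurationError("n_mrna too small for the planted structure")
    module_members: dict[str, list[str]] = {}
    for b in range(config.n_modules):
        label = f"block{b + 1}"
        members = free_mrna[: config.module_size]
        free_mrna = free_mrna[config.module_size:]
        module_members[label] = members
        for gname in members:
            truth.module_map[gname] = label

    regulators = list(rng.choice(mi, size=config.n_regulator_mirnas, replace=False))
    target_pool = free_mrna[: config.n_regulator_mirnas * config.targets_per_regulator]
    free_mrna = free_mrna[len(target_pool):]
    for k, reg in enumerate(regulators):
        tg = target_pool[k * config.targets_per_regulator:(k + 1) * config.targets_per_regulator]
        truth.regulator_map[reg] = set(tg)

    # regulator targets are DE mRNAs (the network stage correlates
    # expressed miRNAs against DE mRNAs only)
    de_candidates = list(target_pool)
    n_de_extra = max(int(round(config.frac_de * (config.n_mrna + config.n_mirna)))
                     - len(de_candidates), 0)
    extra_pool = free_mrna + [m for m in mi if m not in regulators]
    de_extra = list(rng.choice(extra_pool, size=min(n_de_extra, len(extra_pool)),
                               replace=False))
    signs = rng.choice([-1.0, 1.0], size=len(de_candidates) + len(de_extra))
    for gname, s in zip(de_candidates + de_extra, signs):
        truth.de_genes[gname] = float(s * config.de_log2fc_magnitude)

    dd_pool = [g for g in free_mrna + mi if g not in truth.de_genes
               and g not in regulators]
    n_dd = int(round(config.frac_dd * (config.n_mrna + config.n_mirna)))
    for gname in rng.choice(dd_pool, size=min(n_dd, len(dd_pool)), replace=False):
        truth.dd_genes[str(gname)] = float(config.dd_dispersion_fc)

    # --- expression model ---------------------------------------------
    n_samples = n1 + n2
    lib = config.mean_library_size * np.exp(
        rng.uniform(math.log(1.0 - config.library_spread),
                    math.log(1.0 + config.library_spread), size=n_samples)
    )
    bcv_by_biotype = dict(zip(BIOTYPES, config.bcv))
    base_by_biotype = dict(zip(BIOTYPES, config.baseline_log2cpm))

    base_log2cpm = pd.Series(
        [rng.normal(base_by_biotype[biotype[gname]], config.baseline_sd) for gname in genes],
        index=genes,
    )
    # planted targets, regulators and module members portray clearly
    # quantifiable genes: floor their abundance at the biotype mean so
    # shot noise does not drown the planted biological coupling
    planted = set(target_pool) | set(regulators) | set(truth.module_map)
    for gname in planted:
        floor = base_by_biotype[biotype[gname]]
        if base_log2cpm[gname] < floor:
            base_log2cpm[gname] = floor
    truth.baseline_log2cpm = {g: float(base_log2cpm[g]) for g in genes}
    truth.library_sizes = dict(zip(samples, lib))
    module_factors = {lab: rng.normal(size=n_samples) for lab in module_members}

    counts = np.zeros((len(genes), n_samples), dtype=np.int64)
    for gi, gname in enumerate(genes):
        phi = bcv_by_biotype[biotype[gname]] ** 2
        mu = 2.0 ** base_log2cpm[gname] * lib / 1e6
        if gname in truth.de_genes:
            mu = np.where(in_group2, mu * 2.0 ** truth.de_genes[gname], mu)
        phi_s = np.full(n_samples, phi)
        if gname in truth.dd_genes:
            phi_s = np.where(in_group2, phi * truth.dd_genes[gname], phi_s)
        if gname in truth.module_map:
            # shared log-normal biological factor, moment-matched (CV^2 = phi)
            sigma = np.sqrt(np.log1p(phi_s))
            rho = config.module_rho
            zshared = module_factors[truth.module_map[gname]]
            zown = rng.normal(size=n_samples)
            z = math.sqrt(rho) * zshared + math.sqrt(1.0 - rho) * zown
            lam = mu * np.exp(sigma * z - sigma ** 2 / 2.0)
        else:
            shape = 1.0 / np.maximum(phi_s, 1e-12)  # phi = 0 degenerates to Poisson
            lam = mu * rng.gamma(shape, 1.0 / shape)
        counts[gi] = rng.poisson(lam)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        biotype=biotype, group=group,
    )
    return matrix, truth


def simulate_regulation(
    matrix: ExpressionMatrix, truth: GroundTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Redraw target-mRNA counts with repression by their regulator miRNA.

    The regulator's latent per-sample activity is its own realised log2
    expression (shared noise); a target's biological log-component is
    -sqrt(coupling) times that activity plus sqrt(1-coupling) independent
    noise, so repression appears as negative cross-sample correlation of
    roughly -sqrt(coupling_strength).
    """
    rng = np.random.default_rng(config.seed + 1)
    counts = matrix.counts.copy()
    lib = np.array([truth.library_sizes[s] for s in counts.columns])
    in_group2 = (matrix.group == config.group_labels[1]).to_numpy()
    c = config.coupling_strength
    phi = dict(zip(BIOTYPES, np.asarray(config.bcv) ** 2))["mRNA"]
    sigma = math.sqrt(math.log1p(phi))

    for reg, targets in truth.regulator_map.items():
        if reg not in counts.index:
            raise KeyError(f"regulator {reg!r} absent from the count matrix")
        reg_log = np.log2(counts.loc[reg].to_numpy(dtype=float) / lib * 1e6 + 0.5)
        z_reg = (reg_log - reg_log.mean()) / max(reg_log.std(), 1e-12)
        for tgt in sorted(targets):
            if tgt not in counts.index:
                raise KeyError(f"target {tgt!r} absent from the count matrix")
            # rebuild the target's mean model (planted baseline + DE shift)
            base_mu = _baseline_mean(tgt, lib, in_group2, truth)
            eps = rng.normal(size=len(z_reg))
            z = -math.sqrt(c) * z_reg + math.sqrt(1.0 - c) * eps
            lam = base_mu * np.exp(sigma * z - sigma ** 2 / 2.0)
            counts.loc[tgt] = rng.poisson(lam)
    return ExpressionMatrix(counts=counts, biotype=matrix.biotype.copy(),
                            group=matrix.group.copy())


def _baseline_mean(gene: str, lib: np.ndarray, in_group2: np.ndarray,
                   truth: GroundTruth) -> np.ndarray:
    """Per-sample expected counts of a gene from the planted mean model."""
    mu = 2.0 ** truth.baseline_log2cpm[gene] * lib / 1e6
    if gene in truth.de_genes:
        mu = np.where(in_group2, mu * 2.0 ** truth.de_genes[gene], mu)
    return mu


_DNA = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def simulate_sequences(
    truth: GroundTruth, config: SimulationConfig, max_tries: int = 200
) -> tuple[dict[str, str], dict[str, str]]:
    """Mature miRNA sequences (RNA, 22 nt) and 3'-UTRs with planted sites.

    Every target UTR carries its regulator's 7mer-m8 site at a recorded
    position; rejection sampling guarantees that no UTR carries any
    unplanned site for any simulated regulator.  Results are stored on the
    truth object and returned.
    """
    if not truth.regulator_map:
        raise ConfigurationError("regulator_map must be populated before sequences")
    rng = np.random.default_rng(config.seed + 2)
    mr, mi, li = _gene_ids(config)

    matures: dict[str, str] = {}
    sites: dict[str, str] = {}
    regulators = sorted(truth.regulator_map)
    for m in mi:
        for _ in range(max_tries):
            seq = _random_seq(rng, 22).replace("T", "U")
            site = seed_site(seq)
            if m in regulators and site in sites.values():
                continue  # regulator seeds must be distinguishable
            matures[m] = seq
            if m in regulators:
                sites[m] = site
            break
        else:
            raise RuntimeError("could not draw a distinct regulator seed")
    reg_sites = [sites[m] for m in regulators]

    target_of = {t: reg for reg, ts in truth.regulator_map.items() for t in ts}
    utrs: dict[str, str] = {}
    truth.planted_sites = []
    for gname in mr:
        for _ in range(max_tries):
            utr = _random_seq(rng, config.utr_length)
            if any(scan_sites(s, utr) for s in reg_sites):
                continue
            if gname in target_of:
                reg = target_of[gname]
                pos = int(rng.integers(1, config.utr_length - 7 + 2))  # 1-based
                utr = utr[: pos - 1] + sites[reg] + utr[pos + 6:]
                planted_ok = all(
                    scan_sites(s, utr) == ([pos] if s == sites[reg] else [])
                    for s in reg_sites
                )
                if not planted_ok:
                    continue
                truth.planted_sites.append((gname, pos, reg))
            utrs[gname] = utr
            break
        else:
            raise RuntimeError(f"rejection sampling failed for UTR of {gname}")

    truth.mirna_sequences = matures
    truth.utr_sequences = utrs
    return matures, utrs


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_phenotypes(
    matrix: ExpressionMatrix, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Sample x trait phenotype table coupled to planted modules.

    Trait t_k (k = 1..n_modules, capped at n_traits) equals the eigengene
    of planted block k scaled by sqrt(trait_r2) plus Gaussian noise of
    variance 1 - trait_r2; remaining traits are independent standard
    noise.
    """
    if not truth.module_map:
        raise ConfigurationError("module_map must define at least one planted module")
    rng = np.random.default_rng(config.seed + 3)
    lib = matrix.counts.sum(axis=0).to_numpy(dtype=float)
    logcpm = np.log2(matrix.counts / lib * 1e6 + 0.5)

    blocks = sorted(set(truth.module_map.values()))
    n_coupled = min(len(blocks), config.n_traits)
    r2 = config.trait_r2
    data = {}
    truth.trait_module_map = {}
    for k in range(config.n_traits):
        name = f"trait_{k + 1}"
        noise = rng.normal(size=matrix.n_samples)
        if k < n_coupled:
            members = [g for g, b in truth.module_map.items() if b == blocks[k]]
            me = module_eigengene(logcpm, members).to_numpy()
            data[name] = math.sqrt(r2) * me + math.sqrt(1.0 - r2) * noise
            truth.trait_module_map[name] = blocks[k]
        else:
            data[name] = noise
    return pd.DataFrame(data, index=matrix.sample_ids)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth, pd.DataFrame]:
    """Full generator: counts, regulation, sequences and phenotypes."""
    matrix, truth = simulate_counts(config)
    matrix = simulate_regulation(matrix, truth, config)
    simulate_sequences(truth, config)
    phenotypes = simulate_phenotypes(matrix, truth, config)
    return matrix, truth, phenotypes


def write_dataset(outdir, matrix: ExpressionMatrix, truth: GroundTruth,
                  phenotypes: pd.DataFrame, config: SimulationConfig) -> None:
    """Write the synthetic dataset in the pipeline's on-disk formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.counts.rename_axis("gene_id").to_csv(out / "counts.tsv", sep="\t")
    matrix.biotype.rename_axis("gene_id").to_frame().to_csv(out / "biotypes.tsv", sep="\t")
    matrix.group.rename_axis("sample_id").to_frame().to_csv(out / "groups.tsv", sep="\t")
    phenotypes.rename_axis("sample_id").to_csv(out / "phenotypes.csv")
    write_fasta(truth.mirna_sequences, out / "mirna_mature.fa")
    write_fasta(truth.utr_sequences, out / "utrs.fa")
    pd.DataFrame(
        [(g, fc) for g, fc in sorted(truth.de_genes.items())],
        columns=["gene_id", "true_log2fc"],
    ).to_csv(out / "truth_de.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, fc) for g, fc in sorted(truth.dd_genes.items())],
        columns=["gene_id", "true_dispersion_fc"],
    ).to_csv(out / "truth_dd.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m, t) for m, ts in sorted(truth.regulator_map.items()) for t in sorted(ts)],
        columns=["mirna_id", "target_id"],
    ).to_csv(out / "truth_regulators.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.planted_sites, columns=["mrna_id", "position", "mirna_id"]
    ).to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, b) for g, b in sorted(truth.module_map.items())],
        columns=["gene_id", "block"],
    ).to_csv(out / "truth_modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t, b) for t, b in sorted(truth.trait_module_map.items())],
        columns=["trait", "block"],
    ).to_csv(out / "truth_traits.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        import yaml

        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(config).items()}, fh, sort_keys=True)
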