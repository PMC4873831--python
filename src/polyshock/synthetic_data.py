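"""Synthetic allopolyploid expression and homeolog data with planted truth.

The generator emulates the study design the pipeline is built for: two
diploid parents (A and B subgenome donors) profiled with replicates, a
physical 1:1 parental RNA mix serving as the mid-parent reference, a
synthetic allopolyploid followed over consecutive selfed generations, and a
panel of natural allopolyploid accessions assayed for homeolog allele
fractions.  Every classification the pipeline makes — parental divergence
(PEC/PED), additivity vs the mid-parent value, ELD/TRE pattern,
transgenerational consistency, and homeolog-partitioning outcome — has a
planted ground-truth label, so parameter recovery can be scored exactly.

Expression replicate noise is Normal on the log2 scale; allele-fraction
replicate noise is Normal on the logit scale.  The mix is simulated as the
linear-scale average of the parental means, log2((2^a + 2^b)/2), because a
1:1 RNA pool averages transcript quantities, not log intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .iolayer import ExpressionDataset, HomeologTable

__all__ = [
    "SimConfig",
    "HomeologSimConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_homeolog",
]

#: Planted pattern labels a PEC gene may receive (no parental divergence, so
#: parental dominance is undefined; only TRE can be nonadditive).
PEC_PATTERNS = ("constant", "over_tre", "under_tre")
#: Planted pattern labels a PED gene may receive.
PED_PATTERNS = ("additive", "eld_parentA", "eld_parentB", "over_tre", "under_tre")
ADDITIVE_PATTERNS = ("constant", "additive")

PARTITIONING_OUTCOMES = ("unaltered", "erasure", "novel_bias")


@dataclass(frozen=True)
class HomeologSimConfig:
    """Allele-fraction (pyrosequencing analog) simulation settings.

    Outcome weights emulate the reported mid-range mix of stable /
    bias-erased / newly biased loci; ``mix_bias`` is the parental-ortholog
    bias magnitude (mix mean 0.5 +/- mix_bias for biased loci) and
    ``bias_shift`` the planted novel bias (must be < 0.5).  ``noise_sd`` is
    the replicate standard deviation on the logit scale.
    """

    n_genes: int = 150
    reps: int = 3
    frac_unaltered: float = 0.45
    frac_erasure: float = 0.33
    frac_novel_bias: float = 0.22
    bias_shift: float = 0.20
    mix_bias: float = 0.25
    noise_sd: float = 0.15
    frac_mix_biased_unaltered: float = 0.5
    natural_genotypes: tuple[str, ...] = ("TD01", "TD02", "TTR01", "TTR02")
    natural_n_genes: int = 66
    natural_mean_fraction: float = 0.60
    natural_gene_sd: float = 0.40


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated experiment.

    Defaults mirror the emulated design: 3 biological replicates, four
    consecutive selfed generations (S5-S8), two tissues, ~70% of genes with
    diverged parental expression, and a category mix in which additive
    expression is the majority, TRE outweighs ELD, and over-TRE outweighs
    under-TRE.  ``frac_transgen_consistent`` is the share of nonadditive
    genes that keep their planted pattern in every generation; the rest
    re-draw a pattern independently per generation ("ongoing shock").
    """

    n_genes: int = 2000
    n_reps: int = 3
    generations: tuple[str, ...] = ("S5", "S6", "S7", "S8")
    tissues: tuple[str, ...] = ("leaf", "inflorescence")
    frac_ped: float = 0.70
    ped_lfc_range: tuple[float, float] = (1.5, 4.0)
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "constant": 0.25,
            "additive": 0.30,
            "eld_parentA": 0.08,
            "eld_parentB": 0.07,
            "over_tre": 0.20,
            "under_tre": 0.10,
        }
    )
    frac_transgen_consistent: float = 0.40
    replicate_sd: float = 0.25
    tre_delta_range: tuple[float, float] = (1.5, 3.0)
    tre_separation: float = 4.0
    baseline_range: tuple[float, float] = (4.0, 12.0)
    homeolog: HomeologSimConfig = field(default_factory=HomeologSimConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_reps < 1:
            raise ValueError("n_genes and n_reps must be positive")
        if not 0 <= self.frac_ped <= 1:
            raise ValueError("frac_ped must lie in [0, 1]")
        if not 0 <= self.frac_transgen_consistent <= 1:
            raise ValueError("frac_transgen_consistent must lie in [0, 1]")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be nonnegative")
        unknown = set(self.category_mix) - set(PEC_PATTERNS) - set(PED_PATTERNS)
        if unknown:
            raise ValueError(f"unknown category_mix keys: {sorted(unknown)}")
        w = np.array([self.category_mix.get(k, 0.0) for k in set(PEC_PATTERNS) | set(PED_PATTERNS)])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("category_mix weights must be nonnegative and sum to > 0")
        eld = self.category_mix.get("eld_parentA", 0.0) + self.category_mix.get("eld_parentB", 0.0)
        if eld > 0 and self.frac_ped == 0:
            raise ValueError(
                "ELD patterns require diverged parents: eld weights > 0 with frac_ped = 0"
            )
        h = self.homeolog
        if not 0 < h.bias_shift < 0.5:
            raise ValueError("homeolog bias_shift must lie in (0, 0.5)")
        hw = np.array([h.frac_unaltered, h.frac_erasure, h.frac_novel_bias])
        if (hw < 0).any() or hw.sum() <= 0:
            raise ValueError("homeolog outcome weights must be nonnegative and sum to > 0")
        if not 0 < h.mix_bias < 0.5:
            raise ValueError("homeolog mix_bias must lie in (0, 0.5)")


@dataclass
class GroundTruth:
    """Planted labels the pipeline is scored against.

    ``parental``: per gene — PEC/PED status and true parental log2 offset.
    ``patterns``: per gene x tissue x generation — planted pattern label and
    whether the gene was planted as transgenerationally consistent.
    ``homeolog``: per assayed gene — planted partitioning outcome and the
    true mix / polyploid A-fractions (filled by :func:`simulate_homeolog`).
    """

    parental: pd.DataFrame
    patterns: pd.DataFrame
    homeolog: pd.DataFrame | None = None

    def consistent_gene_set(self, tissue: str, generations=None) -> set[str]:
        """Genes whose realized planted pattern is nonadditive and identical
        in every generation (the de facto transgenerational truth)."""
        sub = self.patterns[self.patterns["tissue"] == tissue]
        if generations is not None:
            sub = sub[sub["generation"].isin(list(generations))]
        wide = sub.pivot(index="gene_id", columns="generation", values="pattern")
        same = wide.nunique(axis=1) == 1
        nonadd = ~wide.iloc[:, 0].isin(ADDITIVE_PATTERNS)
        return set(wide.index[same & nonadd & wide.notna().all(axis=1)])


def _sample_id(role: str, tissue: str, generation: str, rep: int) -> str:
    gen = f"_{generation}" if generation else ""
    return f"{role}_{tissue}{gen}_r{rep}"


def _draw_patterns(rng, ped: np.ndarray, mix: dict[str, float], idx: np.ndarray) -> np.ndarray:
    """Draw a planted pattern for each gene index, honoring the expression
    space: ELD is only available to PED genes."""
    out = np.empty(idx.size, dtype=object)
    for is_ped, allowed in ((False, PEC_PATTERNS), (True, PED_PATTERNS)):
        sel = np.flatnonzero(ped[idx] == is_ped)
        if sel.size == 0:
            continue
        w = np.array([mix.get(k, 0.0) for k in allowed], dtype=float)
        if w.sum() <= 0:
            status = "PED" if is_ped else "PEC"
            raise ValueError(
                f"category_mix leaves {status} genes with no admissible pattern"
            )
        out[sel] = rng.choice(allowed, size=sel.size, p=w / w.sum())
    return out


def _pattern_means(pattern, a, b, mix_mean, delta):
    """True polyploid log2 mean implied by each planted pattern."""
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    mean = np.where(pattern == "additive", mix_mean, np.nan)
    mean = np.where(pattern == "constant", mix_mean, mean)  # PEC: a == b == mix
    mean = np.where(pattern == "eld_parentA", a, mean)
    mean = np.where(pattern == "eld_parentB", b, mean)
    mean = np.where(pattern == "over_tre", hi + delta, mean)
    mean = np.where(pattern == "under_tre", lo - delta, mean)
    return mean


def simulate_expression(config: SimConfig, rng=None) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the expression matrix + manifest and its planted truth.

    Per gene: a baseline log2 mean ~ Uniform(baseline_range) per tissue; PED
    genes get a parental offset of magnitude in ``ped_lfc_range`` with random
    sign (split symmetrically about the baseline), PEC genes offset 0.  Mix
    samples follow the linear-scale parental average; polyploid samples
    follow the planted per-generation pattern; replicates add
    Normal(0, replicate_sd) noise.  Deterministic for a fixed seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(1, n + 1)])

    ped = rng.random(n) < config.frac_ped
    mag = rng.uniform(*config.ped_lfc_range, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    lfc = np.where(ped, mag * sign, 0.0)

    parental = pd.DataFrame(
        {
            "gene_id": genes,
            "status": np.where(ped, "PED", "PEC"),
            "parent_lfc": lfc,
        }
    )

    # TRE offset: at least 2 * replicate_sd * tre_separation so planted
    # transgressive genes stay resolvable at the configured noise level.
    lo = max(config.tre_delta_range[0], 2.0 * config.replicate_sd * config.tre_separation)
    hi = max(config.tre_delta_range[1], lo + 0.5)

    manifest_rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    pattern_rows: list[pd.DataFrame] = []

    def add_samples(role, tissue, generation, means):
        for r in range(1, config.n_reps + 1):
            sid = _sample_id(role, tissue, generation, r)
            noise = rng.normal(0.0, config.replicate_sd, size=n) if config.replicate_sd > 0 else 0.0
            columns[sid] = means + noise
            manifest_rows.append(
                {
                    "sample_id": sid,
                    "role": role,
                    "tissue": tissue,
                    "generation": generation,
                    "replicate": r,
                }
            )

    for t_i, tissue in enumerate(config.tissues):
        base = rng.uniform(*config.baseline_range, size=n)
        a = base + lfc / 2.0
        b = base - lfc / 2.0
        mix_mean = np.log2((2.0**a + 2.0**b) / 2.0)
        delta = rng.uniform(lo, hi, size=n)

        all_idx = np.arange(n)
        base_pattern = _draw_patterns(rng, ped, config.category_mix, all_idx)
        nonadd = ~np.isin(base_pattern, ADDITIVE_PATTERNS)
        consistent = nonadd & (rng.random(n) < config.frac_transgen_consistent)
        redraw = nonadd & ~consistent

        add_samples("parentA", tissue, "", a)
        add_samples("parentB", tissue, "", b)
        add_samples("mix", tissue, "", mix_mean)

        for gen in config.generations:
            pattern = base_pattern.copy()
            ridx = np.flatnonzero(redraw)
            if ridx.size:
                pattern[ridx] = _draw_patterns(rng, ped, config.category_mix, ridx)
            poly_mean = _pattern_means(pattern, a, b, mix_mean, delta)
            add_samples("polyploid", tissue, gen, poly_mean)
            pattern_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "tissue": tissue,
                        "generation": gen,
                        "pattern": pattern,
                        "consistent": consistent,
                    }
                )
            )

        if t_i == 0:
            # Natural accessions carry expression columns so a single
            # manifest covers both the matrix and the homeolog table; their
            # total expression is not classified downstream.
            for geno in config.homeolog.natural_genotypes:
                add_samples("natural", tissue, geno, mix_mean)

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    manifest = pd.DataFrame(manifest_rows).set_index("sample_id", drop=False)
    manifest.index.name = None
    dataset = ExpressionDataset(values=values, manifest=manifest)
    truth = GroundTruth(
        parental=parental,
        patterns=pd.concat(pattern_rows, ignore_index=True),
    )
    return dataset, truth


def simulate_homeolog(config: SimConfig, truth: GroundTruth, rng=None) -> HomeologTable:
    """Simulate the allele-fraction table for the first configured tissue.

    Per assayed gene one partitioning outcome is planted: ``unaltered``
    (polyploid keeps the mix fraction), ``erasure`` (a biased mix fraction
    returns to 0.5), or ``novel_bias`` (an unbiased mix fraction moves to
    0.5 +/- bias_shift).  Natural accessions get per-gene mean fractions
    centered on ``natural_mean_fraction`` (overall A-subgenome dominance).
    Updates ``truth.homeolog`` in place and returns the table.
    """
    config.validate()
    h = config.homeolog
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    tissue = config.tissues[0]
    pool = truth.parental["gene_id"].to_numpy()
    m = min(h.n_genes, pool.size)
    genes = np.sort(rng.choice(pool, size=m, replace=False))

    w = np.array([h.frac_unaltered, h.frac_erasure, h.frac_novel_bias], dtype=float)
    outcome = rng.choice(PARTITIONING_OUTCOMES, size=m, p=w / w.sum())
    side = rng.choice([-1.0, 1.0], size=m)
    mix_biased_unaltered = rng.random(m) < h.frac_mix_biased_unaltered

    mix_frac = np.full(m, 0.5)
    mix_frac[outcome == "erasure"] = 0.5 + h.mix_bias * side[outcome == "erasure"]
    ub = (outcome == "unaltered") & mix_biased_unaltered
    mix_frac[ub] = 0.5 + h.mix_bias * side[ub]

    poly_frac = np.full(m, 0.5)
    poly_frac[outcome == "unaltered"] = mix_frac[outcome == "unaltered"]
    nb = outcome == "novel_bias"
    poly_frac[nb] = 0.5 + h.bias_shift * side[nb]

    def noisy(mean: np.ndarray) -> np.ndarray:
        if h.noise_sd > 0:
            vals = expit(logit(mean) + rng.normal(0.0, h.noise_sd, size=mean.shape))
        else:
            vals = mean.copy()
        return np.clip(vals, 0.01, 0.99)

    rows: list[pd.DataFrame] = []

    def add(sample_id: str, vals: np.ndarray, gene_ids: np.ndarray) -> None:
        rows.append(
            pd.DataFrame(
                {"gene_id": gene_ids, "sample_id": sample_id, "a_fraction": vals}
            )
        )

    for r in range(1, h.reps + 1):
        add(_sample_id("mix", tissue, "", r), noisy(mix_frac), genes)
    for gen in config.generations:
        for r in range(1, h.reps + 1):
            add(_sample_id("polyploid", tissue, gen, r), noisy(poly_frac), genes)

    nat_m = min(h.natural_n_genes, m)
    nat_genes = genes[:nat_m]
    for geno in h.natural_genotypes:
        nat_mean = expit(
            logit(np.full(nat_m, h.natural_mean_fraction))
            + rng.normal(0.0, h.natural_gene_sd, size=nat_m)
        )
        for r in range(1, h.reps + 1):
            add(_sample_id("natural", tissue, geno, r), noisy(nat_mean), nat_genes)

    truth.homeolog = pd.DataFrame(
        {
            "gene_id": genes,
            "outcome": outcome,
            "mix_fraction": mix_frac,
            "poly_fraction": poly_frac,
        }
    )
    frame = pd.concat(rows, ignore_index=True)
    return HomeologTable(frame)
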