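"""End-to-end orchestration: counts -> fitness -> epistasis -> features -> screen.

`analyze_competition_table` is the analytic core shared by the library,
the CLI and the simulator-driven studies: it estimates per-replicate
relative fitness, applies the median normalization cascade against the
plasmid-free wild type, computes replicate-level epistasis for every
genotype, classifies each plasmid-mutation combination against the
wild-type epsilon group (ANOVA + Tukey), and tests for sign epistasis.

`run_pipeline` wraps that core with input handling (simulate or load),
the plasmid feature computations, the feature-vs-cost Spearman screen,
file output with provenance headers, and a text report.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .epistasis import (
    classify_epistasis,
    epistasis,
    epistasis_replicates,
    expected_fitness,
    test_sign_epistasis,
)
from . import features as ft
from . import simulate as sim
from .fitness import (
    CompetitionRecord,
    FitnessEstimate,
    median,
    normalize_to_plasmid_free,
    percent_cost,
    relative_fitness,
)
from .stats import StatResult, one_way_anova, spearman

__all__ = [
    "AnalysisResult",
    "PipelineConfig",
    "PipelineResult",
    "analyze_competition_table",
    "feature_cost_screen",
    "run_pipeline",
    "summary_report",
]


def _genotype_of(row) -> sim.Genotype:
    def norm(v):
        return None if (v is None or (isinstance(v, float) and np.isnan(v)) or v == "") else v

    return (norm(row["plasmid"]), norm(row["mutation"]))


@dataclass
class AnalysisResult:
    """Fitness and epistasis tables plus the intermediate replicate groups."""

    fitness: pd.DataFrame
    epistasis: pd.DataFrame
    anova: StatResult
    normalized: Dict[sim.Genotype, FitnessEstimate]
    epsilon_groups: Dict[sim.Genotype, np.ndarray]
    log: List[str] = field(default_factory=list)

    @property
    def wildtype_median_epsilon(self) -> float:
        """Median epsilon of the wild type: exactly 0 by construction.

        Evaluated median-first (median(W)/median(W) - 1), which is the
        numerically exact order for the self-normalized wild type.
        """
        return self.normalized[sim.WILDTYPE].w - 1.0


def analyze_competition_table(
    df: pd.DataFrame,
    alpha: float = 0.05,
    use_latent: bool = False,
    pseudocount: bool = False,
    carrier_normalize: bool = False,
) -> AnalysisResult:
    """Run the full fitness/epistasis analysis on a tidy competition table.

    The table must carry one row per replicate with the four count
    columns and the design columns (plasmid, mutation, replicate); the
    wild type is the genotype with neither label.  Set ``use_latent`` to
    analyze the simulator's noise-free counts instead of the sampled ones.
    """
    log: List[str] = [f"input rows: {len(df)}"]
    count_cols = sim.LATENT_COLUMNS if use_latent else sim.COUNT_COLUMNS

    raw: Dict[sim.Genotype, List[FitnessEstimate]] = {}
    for _, row in df.iterrows():
        g = _genotype_of(row)
        rec = CompetitionRecord(
            n_initial_gfp_neg=row[count_cols[0]],
            n_initial_gfp_pos=row[count_cols[1]],
            n_final_gfp_neg=row[count_cols[2]],
            n_final_gfp_pos=row[count_cols[3]],
            plasmid=g[0],
            mutation=g[1],
            replicate=row.get("replicate"),
        )
        raw.setdefault(g, []).append(relative_fitness(rec, pseudocount=pseudocount))
    if sim.WILDTYPE not in raw:
        raise ValueError("no plasmid-free wild-type rows: cannot normalize")
    log.append(f"genotypes: {len(raw)}")

    control = raw[sim.WILDTYPE]
    normalized = {g: normalize_to_plasmid_free(reps, control) for g, reps in raw.items()}

    fitness_rows = []
    for g, reps in raw.items():
        for est in reps:
            fitness_rows.append(
                {
                    "plasmid": g[0],
                    "mutation": g[1],
                    "level": "vs_gfp_reference",
                    "replicate": est.replicate,
                    "w": est.w,
                }
            )
        norm = normalized[g]
        for i, w in enumerate(norm.replicates, 1):
            fitness_rows.append(
                {
                    "plasmid": g[0],
                    "mutation": g[1],
                    "level": "vs_plasmid_free_wildtype",
                    "replicate": i,
                    "w": w,
                }
            )
    fitness_df = pd.DataFrame(fitness_rows)

    def marginal(g: sim.Genotype) -> float:
        if g == sim.WILDTYPE:
            return 1.0
        if g not in normalized:
            raise ValueError(f"missing single-determinant genotype {g}")
        return normalized[g].w

    # epsilon is defined for the plasmid-mutation combinations and for the
    # wild type (whose median epsilon is 0 by definition); single-determinant
    # strains have epsilon identically 0 by construction and do not enter
    # the comparison family
    combos = [g for g in normalized if g[0] is not None and g[1] is not None]
    eps_groups: Dict[sim.Genotype, np.ndarray] = {}
    for g in [sim.WILDTYPE, *combos]:
        wp = marginal((g[0], None))
        wm = marginal((None, g[1]))
        eps_groups[g] = epistasis_replicates(normalized[g].replicates, wp, wm)

    if combos:
        anova = one_way_anova(list(eps_groups.values()))
        calls = classify_epistasis(eps_groups, sim.WILDTYPE, alpha=alpha)
    else:
        anova = None
        calls = {}
    epi_rows = []
    for g in combos:
        wp, wm = marginal((g[0], None)), marginal((None, g[1]))
        w_obs = normalized[g].w
        w_exp = expected_fitness(wp, wm)
        cls, p_adj = calls[g]
        sign, sign_p = None, {}
        mutant_g, carrier_g = (None, g[1]), (g[0], None)
        if mutant_g in normalized and carrier_g in normalized:
            sign, sign_p = test_sign_epistasis(
                normalized[g].replicates,
                normalized[mutant_g].replicates,
                normalized[carrier_g].replicates,
                alpha=alpha,
            )
        epi_rows.append(
            {
                "plasmid": g[0],
                "mutation": g[1],
                "w_observed": w_obs,
                "w_expected": w_exp,
                "epsilon": epistasis(w_obs, wp, wm),
                "classification": cls,
                "adjusted_p": p_adj,
                "sign_epistasis": sign,
                "sign_p_vs_mutant": sign_p.get("p_vs_mutant", np.nan),
                "sign_p_vs_carrier": sign_p.get("p_vs_carrier", np.nan),
            }
        )
    epistasis_df = pd.DataFrame(epi_rows)
    if anova is not None:
        log.append(
            f"combinations: {len(combos)}; ANOVA F={anova.statistic:.3f} p={anova.p:.3g}"
        )
    else:
        log.append("no plasmid-mutation combinations: epistasis family skipped")
    return AnalysisResult(
        fitness=fitness_df,
        epistasis=epistasis_df,
        anova=anova,
        normalized=normalized,
        epsilon_groups=eps_groups,
        log=log,
    )


def feature_cost_screen(
    features: pd.DataFrame, costs: Dict[str, float]
) -> pd.DataFrame:
    """Spearman screen of plasmid features against plasmid fitness cost.

    ``features`` is the per-plasmid summary table (label, size_bp,
    gc_percent, mean_cai, optionally copy_number); ``costs`` maps plasmid
    label to percent cost.  Returns one row per feature with rho and p.
    """
    df = features.copy()
    df["cost_percent"] = df["label"].map(costs)
    df = df.dropna(subset=["cost_percent"])
    rows = []
    for feat in ("size_bp", "gc_percent", "mean_cai", "copy_number"):
        if feat not in df or df[feat].isna().any():
            continue
        if len(df) < 3:
            raise ValueError("need at least 3 plasmids for the correlation screen")
        res = spearman(df[feat].to_numpy(), df["cost_percent"].to_numpy())
        rows.append({"feature": feat, "rho": res.statistic, "p": res.p, "n": len(df)})
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    mode: str = "simulate"  # simulate | real
    seed: int = 0
    alpha: float = 0.05
    output_dir: Union[str, Path] = "plasmidcost_out"
    use_latent: bool = False
    pseudocount: bool = False
    # simulate mode
    simulation: Optional[sim.SimulationConfig] = None
    simulate_features: bool = True
    # real mode
    counts_path: Optional[Union[str, Path]] = None
    record_paths: Sequence[Union[str, Path]] = ()
    depth_paths: Sequence[Union[str, Path]] = ()
    codon_table_path: Optional[Union[str, Path]] = None
    chromosome_label: str = "chromosome"

    def __post_init__(self):
        if self.mode not in ("simulate", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for p in [self.counts_path, *self.record_paths, *self.depth_paths]:
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        simcfg = None
        if "simulation" in raw:
            s = raw.pop("simulation")
            shifts = {
                (k.split(":", 1)[0], k.split(":", 1)[1]): v
                for k, v in (s.pop("epistasis_shift", {}) or {}).items()
            }
            simcfg = sim.SimulationConfig.factorial(
                plasmids=s.pop("plasmids"),
                mutations=s.pop("mutations"),
                epistasis_shift=shifts,
                **s,
            )
        return cls(simulation=simcfg, **raw)

    def hash(self) -> str:
        parts = [
            self.mode,
            str(self.seed),
            str(self.alpha),
            str(self.use_latent),
            str(self.pseudocount),
            sim.config_hash(self.simulation) if self.simulation else "-",
            str(self.counts_path),
            ",".join(map(str, self.record_paths)),
            ",".join(map(str, self.depth_paths)),
        ]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything one run produced, with the log of what happened."""

    config: PipelineConfig
    counts: pd.DataFrame
    analysis: AnalysisResult
    features: Optional[pd.DataFrame]
    correlations: Optional[pd.DataFrame]
    log: List[str]


# default true landscape for simulate mode when none is configured: six
# plasmids with 10-30% costs and three slow-translation mutations, as in
# a typical plasmid-by-mutation factorial assay
_DEFAULT_PLASMIDS = {
    "pA": 0.90,
    "pB": 0.85,
    "pC": 0.80,
    "pD": 0.75,
    "pE": 0.72,
    "pF": 0.70,
}
_DEFAULT_MUTATIONS = {"mut1": 0.80, "mut2": 0.70, "mut3": 0.60}


def _simulated_features(
    config: PipelineConfig, plasmids: Sequence[str]
) -> pd.DataFrame:
    table = ft.load_reference_table()
    rows = []
    # decouple feature magnitudes from the plasmid ordering (and hence from
    # any cost gradient in the configured landscape)
    perm = np.random.default_rng(sim.derive_seed(config.seed, (None, None), 777))
    order = perm.permutation(len(plasmids))
    for i, label in zip(order, plasmids):
        rec = sim.simulate_plasmid_record(
            length_bp=20_000 + 10_000 * i,
            gc_fraction=0.46 + 0.03 * i,
            n_orfs=8,
            codon_bias_strength=0.2 + 0.1 * (i % 4),
            seed=sim.derive_seed(config.seed, (label, None), 9999),
            table=table,
            record_id=label,
        )
        depths = sim.simulate_depth_table(
            copy_number=float(1 + 3 * i),
            chrom_mean_depth=100.0,
            noise_cv=0.1,
            seed=sim.derive_seed(config.seed, (label, None), 9998),
        )
        rows.append(ft.plasmid_summary(rec, table, depths.plasmid, depths.chromosome))
    return pd.DataFrame(rows)


def _real_features(config: PipelineConfig) -> Optional[pd.DataFrame]:
    if not config.record_paths:
        return None
    table = (
        ft.build_weight_table(ft.read_codon_table(config.codon_table_path))
        if config.codon_table_path
        else ft.load_reference_table()
    )
    depth_by_label: Dict[str, ft.DepthProfile] = {}
    chrom: Optional[ft.DepthProfile] = None
    for path in config.depth_paths:
        for label, prof in ft.read_depth_table(path).items():
            if label == config.chromosome_label:
                chrom = prof
            else:
                depth_by_label[label] = prof
    rows = []
    for path in config.record_paths:
        fmt = "genbank" if str(path).endswith((".gb", ".gbk", ".genbank")) else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            plas_depth = depth_by_label.get(rec.id)
            rows.append(
                ft.plasmid_summary(
                    rec,
                    table,
                    plas_depth,
                    chrom if plas_depth is not None else None,
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the result bundle to ``config.output_dir``.

    Deterministic under a fixed config: identical reruns produce
    byte-identical output files, each carrying the config hash and seed
    in a header comment.
    """
    log = [f"mode={config.mode} seed={config.seed} alpha={config.alpha}"]
    if config.mode == "simulate":
        simcfg = config.simulation or sim.SimulationConfig.factorial(
            _DEFAULT_PLASMIDS, _DEFAULT_MUTATIONS, seed=config.seed
        )
        counts = sim.simulate_experiment(simcfg)
        log.append(f"simulated {len(counts)} competition replicates")
    else:
        if config.counts_path is None:
            raise ValueError("real mode requires counts_path")
        counts = sim.read_competition_csv(config.counts_path)
        log.append(f"loaded {len(counts)} competition replicates")

    try:
        analysis = analyze_competition_table(
            counts,
            alpha=config.alpha,
            use_latent=config.use_latent,
            pseudocount=config.pseudocount,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'fitness/epistasis' failed: {exc}") from exc
    log.extend(analysis.log)

    features = None
    try:
        if config.mode == "simulate" and config.simulate_features:
            plasmids = sorted(
                {g[0] for g in analysis.normalized if g[0] is not None}
            )
            features = _simulated_features(config, plasmids)
        elif config.mode == "real":
            features = _real_features(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    correlations = None
    if features is not None and len(features) >= 3:
        costs = {
            g[0]: percent_cost(est.w)
            for g, est in analysis.normalized.items()
            if g[0] is not None and g[1] is None
        }
        correlations = feature_cost_screen(features, costs)
        log.append(f"correlation screen over {len(features)} plasmids")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# plasmidcost run config_hash={config.hash()} seed={config.seed}\n"

    def dump(df: Optional[pd.DataFrame], name: str):
        if df is None:
            return
        out = df.copy()
        for col in ("plasmid", "mutation"):
            if col in out:
                out[col] = out[col].fillna("")
        with open(outdir / name, "w") as fh:
            fh.write(header)
            out.to_csv(fh, index=False)
        log.append(f"wrote {name} ({len(df)} rows)")

    dump(counts, "counts.csv")
    dump(analysis.fitness, "fitness.csv")
    dump(analysis.epistasis, "epistasis.csv")
    dump(features, "features.csv")
    dump(correlations, "correlations.csv")

    result = PipelineResult(config, counts, analysis, features, correlations, log)
    (outdir / "report.md").write_text(header + summary_report(result))
    (outdir / "run.log").write_text(header + "\n".join(log) + "\n")
    return result


def summary_report(result: PipelineResult) -> str:
    """Human-readable summary: costs, epistasis class counts, correlations."""
    lines = ["# Competition analysis report", ""]
    lines.append("## Fitness costs (relative to the plasmid-free wild type)")
    lines.append("")
    lines.append("| plasmid | mutation | W (median) | cost % |")
    lines.append("|---|---|---|---|")
    for g in sorted(result.analysis.normalized, key=str):
        est = result.analysis.normalized[g]
        lines.append(
            f"| {g[0] or '-'} | {g[1] or '-'} | {est.w:.4f} | {percent_cost(est.w):.1f} |"
        )
    epi = result.analysis.epistasis
    lines += ["", "## Epistasis (multiplicative null)", ""]
    if len(epi):
        n = len(epi)
        for cls in ("positive", "negative", "none"):
            k = int((epi["classification"] == cls).sum())
            lines.append(f"- {cls}: {k}/{n} combinations")
        k_sign = int(epi["sign_epistasis"].fillna(False).sum())
        lines.append(f"- sign epistasis: {k_sign}/{n} combinations")
        a = result.analysis.anova
        lines.append(
            f"- omnibus ANOVA: F = {a.statistic:.2f}, d.f. = {a.df[0]}, p = {a.p:.3g}"
        )
    else:
        lines.append("- no plasmid-mutation combinations in this design")
    if result.correlations is not None and len(result.correlations):
        lines += ["", "## Feature-vs-cost screen (Spearman)", ""]
        lines.append("| feature | rho | p | n |")
        lines.append("|---|---|---|---|")
        for _, row in result.correlations.iterrows():
            lines.append(
                f"| {row['feature']} | {row['rho']:.3f} | {row['p']:.3f} | {int(row['n'])} |"
            )
    lines.append("")
    return "\n".join(lines)
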