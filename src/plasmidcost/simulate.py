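"""Synthetic competition experiments, toy plasmid records and depth tables.

The competition generator emulates the standard head-to-head assay: a 1:1
mixture of a GFP-negative test strain and the GFP-tagged reference is
diluted 1:400 into fresh medium and grown for one cycle; competitor
proportions before and after growth are measured by flow cytometry at
10,000 events per sample, with six replicates per strain (36 for the
wild type).

Growth model: over one cycle the reference expands by a total factor G
(the dilution factor, 400, so the culture returns to carrying capacity)
and the test strain by G**w, where w is its true relative fitness — the
ratio of Malthusian parameters.  This makes the log-ratio fitness
estimator exact in the noise-free limit.  Optional per-replicate,
per-competitor lognormal noise perturbs the fold-expansions.  Cytometry
is modeled as a two-class multinomial draw at fixed total events; sampled
counts are rescaled to the latent culture size so that counts before and
after growth share a common scale, as the estimator requires.

Plasmid loss and conjugative transfer during the competition (verified
negligible experimentally) are not simulated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .features import (
    CodonUsageTable,
    DepthProfile,
    SYNONYMOUS_FAMILIES,
    load_reference_table,
)
from .fitness import CompetitionRecord

__all__ = [
    "Genotype",
    "WILDTYPE",
    "SimulationConfig",
    "derive_seed",
    "simulate_competition",
    "simulate_experiment",
    "simulate_plasmid_record",
    "simulate_depth_table",
    "DepthTables",
    "write_competition_csv",
    "read_competition_csv",
    "write_depth_table",
    "config_hash",
]

Genotype = Tuple[Optional[str], Optional[str]]

#: the plasmid-free, mutation-free wild type
WILDTYPE: Genotype = (None, None)

COUNT_COLUMNS = [
    "n_initial_gfp_neg",
    "n_initial_gfp_pos",
    "n_final_gfp_neg",
    "n_final_gfp_pos",
]
LATENT_COLUMNS = ["latent_" + c[2:] for c in COUNT_COLUMNS]


@dataclass(frozen=True)
class SimulationConfig:
    """True fitness landscape and assay design for a simulated experiment.

    ``true_w`` holds the marginal fitness of single-determinant genotypes
    (plasmid-only and mutation-only, relative to the wild type, which has
    fitness 1 by construction); combination genotypes get the product of
    their marginals plus the optional additive ``epistasis_shift``.
    """

    genotypes: Tuple[Genotype, ...]
    true_w: Mapping[Genotype, float]
    epistasis_shift: Mapping[Genotype, float] = field(default_factory=dict)
    replicates: int = 6
    wildtype_replicates: int = 36
    expansion_factor: float = 400.0
    events_per_measurement: int = 10_000
    growth_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        genotypes = tuple(tuple(g) for g in self.genotypes)
        object.__setattr__(self, "genotypes", genotypes)
        if WILDTYPE not in genotypes:
            raise ValueError("genotypes must include the (None, None) wild type")
        if len(set(genotypes)) != len(genotypes):
            raise ValueError("duplicate genotypes")
        for g, w in self.true_w.items():
            if not (w > 0):
                raise ValueError(f"true fitness must be > 0, got {w} for {g}")
        if self.true_w.get(WILDTYPE, 1.0) != 1.0:
            raise ValueError("the wild type has true fitness 1 by construction")
        for g in self.epistasis_shift:
            if tuple(g) not in genotypes:
                raise ValueError(f"epistasis_shift genotype {g} not in design")
        if not self.expansion_factor > 1:
            raise ValueError("expansion factor must be > 1")
        if self.events_per_measurement < 1:
            raise ValueError("need at least 1 event per measurement")
        if self.replicates < 1 or self.wildtype_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.growth_noise_sd < 0:
            raise ValueError("growth noise sd must be >= 0")

    @classmethod
    def factorial(
        cls,
        plasmids: Mapping[str, float],
        mutations: Mapping[str, float],
        epistasis_shift: Optional[Mapping[Genotype, float]] = None,
        **kwargs,
    ) -> "SimulationConfig":
        """Full factorial design: wild type, singles, and every combination."""
        genotypes: List[Genotype] = [WILDTYPE]
        true_w: Dict[Genotype, float] = {WILDTYPE: 1.0}
        for p, w in plasmids.items():
            genotypes.append((p, None))
            true_w[(p, None)] = w
        for m, w in mutations.items():
            genotypes.append((None, m))
            true_w[(None, m)] = w
        for p in plasmids:
            for m in mutations:
                genotypes.append((p, m))
        return cls(
            genotypes=tuple(genotypes),
            true_w=true_w,
            epistasis_shift=dict(epistasis_shift or {}),
            **kwargs,
        )

    def n_replicates(self, genotype: Genotype) -> int:
        return self.wildtype_replicates if tuple(genotype) == WILDTYPE else self.replicates

    def true_fitness(self, genotype: Genotype) -> float:
        """True relative fitness of a genotype under the configured landscape."""
        g = tuple(genotype)
        if g == WILDTYPE:
            return 1.0
        if g in self.true_w:
            return float(self.true_w[g])
        plasmid, mutation = g
        try:
            wp = self.true_w[(plasmid, None)] if plasmid is not None else 1.0
            wm = self.true_w[(None, mutation)] if mutation is not None else 1.0
        except KeyError as exc:
            raise ValueError(f"no true fitness for marginal of {g}") from exc
        w = wp * wm + float(self.epistasis_shift.get(g, 0.0))
        if not w > 0:
            raise ValueError(f"configured landscape gives non-positive fitness for {g}")
        return w


def _label_bytes(label: Optional[str]) -> bytes:
    return b"\x00" if label is None else label.encode("utf-8")


def derive_seed(master_seed: int, genotype: Genotype, replicate: int) -> int:
    """Stable per-replicate seed from (master seed, genotype, replicate).

    Uses a SHA-256 hash so the stream assignment is independent of
    execution order and of Python's per-process string hashing.
    """
    h = hashlib.sha256()
    h.update(int(master_seed).to_bytes(8, "little", signed=True))
    h.update(_label_bytes(genotype[0]))
    h.update(b"|")
    h.update(_label_bytes(genotype[1]))
    h.update(int(replicate).to_bytes(8, "little", signed=True))
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


def simulate_competition(
    true_w: float,
    config: SimulationConfig,
    seed: int,
    genotype: Genotype = WILDTYPE,
    replicate: object = None,
) -> CompetitionRecord:
    """Simulate one competition replicate against the GFP reference.

    The latent (noise-free) trajectory starts from a perfect 1:1 mixture
    on a scale of ``events_per_measurement`` total cells; each competitor
    expands by its fold-factor (perturbed by lognormal noise when
    ``growth_noise_sd`` > 0).  Both timepoints are then measured by a
    multinomial draw of ``events_per_measurement`` cytometry events, and
    the sampled proportions are rescaled to the latent culture totals so
    the record's counts share a common scale.
    """
    if not (true_w > 0):
        raise ValueError(f"true fitness must be > 0, got {true_w}")
    g = config.expansion_factor
    if not g > 1:
        raise ValueError(f"expansion factor must be > 1, got {g}")
    rng = np.random.default_rng(seed)
    events = config.events_per_measurement

    n0 = float(events)
    latent_init = np.array([n0 / 2.0, n0 / 2.0])  # [gfp-, gfp+]
    fold = np.array([g**true_w, g])
    if config.growth_noise_sd > 0:
        fold = fold * np.exp(rng.normal(0.0, config.growth_noise_sd, size=2))
    latent_final = latent_init * fold

    sampled_init = rng.multinomial(events, latent_init / latent_init.sum()).astype(float)
    final_total = latent_final.sum()
    sampled_final = (
        rng.multinomial(events, latent_final / final_total).astype(float)
        * final_total
        / events
    )
    return CompetitionRecord(
        n_initial_gfp_neg=sampled_init[0],
        n_initial_gfp_pos=sampled_init[1],
        n_final_gfp_neg=sampled_final[0],
        n_final_gfp_pos=sampled_final[1],
        plasmid=genotype[0],
        mutation=genotype[1],
        replicate=replicate,
        latent_initial_gfp_neg=latent_init[0],
        latent_initial_gfp_pos=latent_init[1],
        latent_final_gfp_neg=latent_final[0],
        latent_final_gfp_pos=latent_final[1],
    )


def simulate_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a full competition experiment under the configured design.

    One block of replicates per genotype, each replicate with its own
    derived seed; deterministic given ``config.seed``.  Returns a tidy
    table with design columns, sampled counts and latent counts.
    """
    rows = []
    for genotype in config.genotypes:
        w = config.true_fitness(genotype)
        for rep in range(1, config.n_replicates(genotype) + 1):
            rec = simulate_competition(
                w,
                config,
                seed=derive_seed(config.seed, genotype, rep),
                genotype=genotype,
                replicate=rep,
            )
            rows.append(
                {
                    "plasmid": genotype[0],
                    "mutation": genotype[1],
                    "replicate": rep,
                    "true_w": w,
                    "n_initial_gfp_neg": rec.n_initial_gfp_neg,
                    "n_initial_gfp_pos": rec.n_initial_gfp_pos,
                    "n_final_gfp_neg": rec.n_final_gfp_neg,
                    "n_final_gfp_pos": rec.n_final_gfp_pos,
                    "latent_initial_gfp_neg": rec.latent_initial_gfp_neg,
                    "latent_initial_gfp_pos": rec.latent_initial_gfp_pos,
                    "latent_final_gfp_neg": rec.latent_final_gfp_neg,
                    "latent_final_gfp_pos": rec.latent_final_gfp_pos,
                }
            )
    return pd.DataFrame(rows)


def simulate_plasmid_record(
    length_bp: int,
    gc_fraction: float,
    n_orfs: int,
    codon_bias_strength: float,
    seed: int,
    table: Optional[CodonUsageTable] = None,
    record_id: str = "toy_plasmid",
) -> SeqRecord:
    """Generate a circular annotated plasmid record (synthetic fixture).

    ORFs start with ATG, end with a stop codon, have length divisible by
    3, and are annotated as CDS features with strand.  Internal codons
    are drawn per amino acid: with probability ``codon_bias_strength``
    the family's maximal-weight codon under ``table``, otherwise a
    uniformly random synonymous codon.  Intergenic bases are drawn at the
    target GC and then adjusted so the realized GC fraction matches the
    target closely (within 1% for records >= 10 kb).
    """
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    if n_orfs < 0 or length_bp < 1:
        raise ValueError("n_orfs must be >= 0 and length_bp >= 1")
    if not (0 <= codon_bias_strength <= 1):
        raise ValueError("codon_bias_strength must be in [0, 1]")
    if table is None:
        table = load_reference_table()
    rng = np.random.default_rng(seed)

    aas = sorted(SYNONYMOUS_FAMILIES)
    orf_lengths = []
    for _ in range(n_orfs):
        n_codons = int(rng.integers(80, 260))  # internal codons
        orf_lengths.append(3 * (n_codons + 2))  # + start + stop
    total_orf = sum(orf_lengths)
    if total_orf > length_bp:
        raise ValueError(
            f"cannot pack {n_orfs} ORFs ({total_orf} bp) into {length_bp} bp"
        )

    # distribute intergenic space as n_orfs+1 gaps
    free = length_bp - total_orf
    if n_orfs:
        cuts = np.sort(rng.integers(0, free + 1, size=n_orfs))
        gaps = np.diff(np.concatenate([[0], cuts, [free]]))
    else:
        gaps = np.array([free])

    def orf_seq(n_internal: int) -> str:
        codons = ["ATG"]
        for _ in range(n_internal):
            aa = aas[rng.integers(len(aas))]
            fam = SYNONYMOUS_FAMILIES[aa]
            if rng.random() < codon_bias_strength:
                codons.append(table.optimal_codon(aa))
            else:
                codons.append(fam[rng.integers(len(fam))])
        codons.append("TAA")
        return "".join(codons)

    bases = "ACGT"
    p_bg = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )

    parts: List[str] = []
    features: List[SeqFeature] = []
    gap_spans: List[Tuple[int, int]] = []
    pos = 0
    for i in range(n_orfs + 1):
        gap = int(gaps[i])
        if gap:
            seq = "".join(bases[j] for j in rng.choice(4, size=gap, p=p_bg))
            parts.append(seq)
            gap_spans.append((pos, pos + gap))
            pos += gap
        if i < n_orfs:
            n_internal = orf_lengths[i] // 3 - 2
            coding = orf_seq(n_internal)
            strand = 1 if rng.random() < 0.5 else -1
            genomic = coding if strand == 1 else str(Seq(coding).reverse_complement())
            parts.append(genomic)
            features.append(
                SeqFeature(
                    FeatureLocation(pos, pos + len(genomic), strand=strand),
                    type="CDS",
                    qualifiers={"locus_tag": [f"ORF{i + 1:03d}"]},
                )
            )
            pos += len(genomic)

    seq_arr = np.frombuffer("".join(parts).encode(), dtype="S1").copy()
    # nudge intergenic bases so realized GC hits the target
    target_gc = round(gc_fraction * length_bp)
    current_gc = int(np.isin(seq_arr, [b"G", b"C"]).sum())
    delta = target_gc - current_gc
    if delta != 0 and gap_spans:
        gap_idx = np.concatenate([np.arange(a, b) for a, b in gap_spans])
        rng.shuffle(gap_idx)
        if delta > 0:
            cand = gap_idx[np.isin(seq_arr[gap_idx], [b"A", b"T"])][:delta]
            seq_arr[cand] = np.where(
                rng.random(len(cand)) < 0.5, b"G", b"C"
            )
        else:
            cand = gap_idx[np.isin(seq_arr[gap_idx], [b"G", b"C"])][:-delta]
            seq_arr[cand] = np.where(rng.random(len(cand)) < 0.5, b"A", b"T")
    realized_gc = int(np.isin(seq_arr, [b"G", b"C"]).sum()) / length_bp
    if abs(realized_gc - gc_fraction) > 0.01 and length_bp >= 10_000:
        raise ValueError(
            f"cannot reach GC {gc_fraction:.3f} (got {realized_gc:.3f}): "
            "ORFs leave too little intergenic space"
        )

    record = SeqRecord(
        Seq(seq_arr.tobytes().decode()),
        id=record_id,
        name=record_id[:16],
        description="synthetic circular plasmid fixture",
        features=features,
    )
    record.annotations["topology"] = "circular"
    record.annotations["molecule_type"] = "DNA"
    record.annotations["date"] = "01-JAN-2000"  # fixed for reproducible output
    return record


@dataclass(frozen=True)
class DepthTables:
    """Per-position depth table plus the two summarized profiles."""

    table: pd.DataFrame
    plasmid: DepthProfile
    chromosome: DepthProfile


def simulate_depth_table(
    copy_number: float,
    chrom_mean_depth: float,
    noise_cv: float,
    seed: int,
    n_chromosome_positions: int = 5000,
    n_plasmid_positions: int = 1000,
) -> DepthTables:
    """Simulate per-position sequencing depths for a chromosome and a plasmid.

    Depths are gamma-distributed with the requested coefficient of
    variation (constant when ``noise_cv`` = 0); the plasmid's mean depth
    is ``copy_number`` times the chromosome's, so the depth ratio is an
    unbiased proxy for copy number.
    """
    if not (copy_number > 0 and chrom_mean_depth > 0):
        raise ValueError("copy_number and chrom_mean_depth must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)

    def depths(mean: float, n: int) -> np.ndarray:
        if noise_cv == 0:
            return np.full(n, mean)
        shape = 1.0 / noise_cv**2
        return rng.gamma(shape, mean / shape, size=n)

    d_chrom = depths(chrom_mean_depth, n_chromosome_positions)
    d_plas = depths(copy_number * chrom_mean_depth, n_plasmid_positions)
    table = pd.DataFrame(
        {
            "replicon": ["chromosome"] * n_chromosome_positions
            + ["plasmid"] * n_plasmid_positions,
            "position": list(range(1, n_chromosome_positions + 1))
            + list(range(1, n_plasmid_positions + 1)),
            "depth": np.concatenate([d_chrom, d_plas]),
        }
    )
    return DepthTables(
        table=table,
        plasmid=DepthProfile("plasmid", float(d_plas.mean()), n_plasmid_positions),
        chromosome=DepthProfile(
            "chromosome", float(d_chrom.mean()), n_chromosome_positions
        ),
    )


def config_hash(config: SimulationConfig) -> str:
    """Short stable hash of a simulation configuration (for log headers)."""
    canon = repr(
        (
            sorted((str(g), w) for g, w in config.true_w.items()),
            sorted((str(g), s) for g, s in config.epistasis_shift.items()),
            sorted(str(g) for g in config.genotypes),
            config.replicates,
            config.wildtype_replicates,
            config.expansion_factor,
            config.events_per_measurement,
            config.growth_noise_sd,
            config.seed,
        )
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_competition_csv(
    df: pd.DataFrame,
    path: Union[str, Path],
    config: Optional[SimulationConfig] = None,
    include_latent: bool = True,
) -> None:
    """Write a competition dataset as CSV with a provenance header comment."""
    out = df.copy()
    if not include_latent:
        out = out.drop(columns=[c for c in LATENT_COLUMNS if c in out], errors="ignore")
    for col in ("plasmid", "mutation"):
        out[col] = out[col].fillna("")
    header = "# plasmidcost competition dataset\n"
    if config is not None:
        header += f"# seed={config.seed} config_hash={config_hash(config)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, index=False)


def read_competition_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a competition dataset CSV (the dialect written by this package)."""
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    for col in ("plasmid", "mutation"):
        df[col] = df[col].replace("", None)
    for col in df.columns:
        if col.startswith(("n_", "latent_", "true_")):
            df[col] = df[col].astype(float)
    return df


def write_depth_table(tables: DepthTables, path: Union[str, Path]) -> None:
    """Write per-position depths as 3-column TSV (replicon, position, depth)."""
    tables.table.to_csv(path, sep="\t", index=False, header=False)
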