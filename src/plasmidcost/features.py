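"""Plasmid sequence features: CAI, GC content, size and copy number.

The codon adaptation index (CAI) of an ORF is the geometric mean of the
relative-adaptiveness weights of its codons.  Weights come from a
reference codon-usage table (highly expressed genes of the host): within
each synonymous family the most frequent codon gets weight 1 and every
other codon its frequency relative to that maximum, so CAI = 1 means the
ORF uses only the host's preferred codons.  Zero-frequency sense codons
are floored at a small positive weight so a single rare codon cannot
drive CAI to zero.

Plasmid copy number is proxied by the ratio of mean plasmid sequencing
depth to mean chromosomal sequencing depth from the same library.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import gc_fraction

__all__ = [
    "CodonUsageTable",
    "OrfFeature",
    "DepthProfile",
    "WEIGHT_FLOOR",
    "SENSE_CODONS",
    "STOP_CODONS",
    "SYNONYMOUS_FAMILIES",
    "read_codon_table",
    "load_reference_table",
    "build_weight_table",
    "cai",
    "cai_detail",
    "gc_content",
    "copy_number_proxy",
    "read_depth_table",
    "extract_orfs",
    "orf_features",
    "plasmid_summary",
]

# bacterial genetic code (NCBI table 11); codon->aa assignments match the
# standard code, alternative starts are translated as the literal codon
_TABLE = _CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = frozenset(_TABLE.forward_table)

SYNONYMOUS_FAMILIES: Dict[str, tuple] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: weight assigned to zero-frequency sense codons before the geometric mean
WEIGHT_FLOOR = 0.01


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative-adaptiveness weights per sense codon, max 1 per family."""

    weights: Mapping[str, float]
    source: str = "custom"

    def __post_init__(self):
        missing = SENSE_CODONS - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for sense codons: {sorted(missing)}")
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            wmax = max(self.weights[c] for c in fam)
            if not math.isclose(wmax, 1.0):
                raise ValueError(f"family {aa} has max weight {wmax}, expected 1")
        for c in SENSE_CODONS:
            if not (self.weights[c] > 0):
                raise ValueError(f"non-positive weight for {c}")

    def optimal_codon(self, aa: str) -> str:
        return max(SYNONYMOUS_FAMILIES[aa], key=lambda c: self.weights[c])


@dataclass(frozen=True)
class OrfFeature:
    """Per-ORF coordinates (1-based inclusive) and codon-usage summary."""

    id: str
    start: int
    end: int
    strand: str
    length_codons: int
    cai: float
    n_ambiguous: int = 0


@dataclass(frozen=True)
class DepthProfile:
    """Mean per-position sequencing depth of one replicon."""

    replicon: str
    mean_depth: float
    n_positions: int

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError("mean depth must be >= 0")


def _normalize_codon(codon: str) -> str:
    return codon.upper().replace("U", "T")


def read_codon_table(path: Union[str, Path]) -> Dict[str, float]:
    """Read codon frequencies from an EMBOSS-style .cut file or a 2-column TSV.

    The dialect is auto-detected per line: EMBOSS rows carry
    ``codon aa fraction per-1000 count`` (the count column is used),
    TSV rows carry ``codon<TAB>count``.  Comment lines (``#``) and blank
    lines are ignored; RNA codons (U) are accepted.
    """
    freqs: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("!"):
                continue
            fields = line.split()
            codon = _normalize_codon(fields[0])
            if len(codon) != 3 or any(b not in "ACGT" for b in codon):
                raise ValueError(f"{path}:{lineno}: not a codon: {fields[0]!r}")
            try:
                if len(fields) >= 5:  # EMBOSS layout: use the count column
                    value = float(fields[4])
                elif len(fields) == 2:
                    value = float(fields[1])
                else:
                    raise ValueError
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative frequency")
            freqs[codon] = value
    if len(freqs) != 64:
        raise ValueError(f"{path}: expected 64 codons, found {len(freqs)}")
    return freqs


def load_reference_table(name: str = "ecoli_k12") -> CodonUsageTable:
    """Load a bundled reference codon-usage table by name."""
    ref = resources.files("plasmidcost") / "data" / f"{name}.cut"
    with resources.as_file(ref) as path:
        return build_weight_table(read_codon_table(path), source=name)


def build_weight_table(
    codon_frequencies: Mapping[str, float], source: str = "custom"
) -> CodonUsageTable:
    """Derive relative-adaptiveness weights w(c) = freq(c) / max synonymous freq.

    Frequencies may be counts, per-1000 rates or fractions — only ratios
    within each synonymous family matter.  Zero-frequency sense codons
    (and whole-family zeros, e.g. uniform-zero input) are floored at
    ``WEIGHT_FLOOR``; single-codon families (ATG, TGG) get weight 1.
    """
    freqs = {_normalize_codon(c): float(v) for c, v in codon_frequencies.items()}
    missing = SENSE_CODONS - set(freqs)
    if missing:
        raise ValueError(f"frequencies missing for sense codons: {sorted(missing)}")
    weights: Dict[str, float] = {}
    for fam in SYNONYMOUS_FAMILIES.values():
        fmax = max(freqs[c] for c in fam)
        for c in fam:
            w = freqs[c] / fmax if fmax > 0 else 1.0
            weights[c] = max(w, WEIGHT_FLOOR)
    return CodonUsageTable(weights=weights, source=source)


def _codons(seq: str) -> Iterable[str]:
    for i in range(0, len(seq), 3):
        yield seq[i : i + 3]


def cai_detail(
    orf_sequence: Union[str, Seq], table: CodonUsageTable
) -> tuple[float, int, int]:
    """CAI plus the number of codons included and the number skipped.

    Skipped codons are stop codons (a terminal stop is expected; an
    internal stop triggers a warning but the value is still computed) and
    codons containing ambiguous bases.
    """
    seq = _normalize_codon(str(orf_sequence))
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} is not a positive multiple of 3")
    codons = list(_codons(seq))
    log_sum = 0.0
    n_used = 0
    n_ambiguous = 0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i != len(codons) - 1:
                warnings.warn(
                    f"internal stop codon {codon} at codon {i + 1}", stacklevel=2
                )
            continue
        if codon not in SENSE_CODONS:
            n_ambiguous += 1
            continue
        log_sum += math.log(table.weights[codon])
        n_used += 1
    if n_used == 0:
        raise ValueError("no scorable codons in ORF")
    return math.exp(log_sum / n_used), n_used, n_ambiguous


def cai(orf_sequence: Union[str, Seq], table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of codon weights, in (0, 1]."""
    return cai_detail(orf_sequence, table)[0]


def gc_content(sequence: Union[str, Seq]) -> float:
    """GC content as a percentage; ambiguity codes are excluded entirely."""
    seq = str(sequence)
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return 100.0 * gc_fraction(Seq(seq), ambiguous="remove")


def copy_number_proxy(plasmid: DepthProfile, chromosome: DepthProfile) -> float:
    """Plasmid copy number proxy: mean plasmid depth / mean chromosome depth."""
    if chromosome.mean_depth <= 0:
        raise ValueError("chromosome mean depth must be > 0")
    return plasmid.mean_depth / chromosome.mean_depth


def read_depth_table(path: Union[str, Path]) -> Dict[str, DepthProfile]:
    """Read a 3-column TSV (replicon, position, depth; 1-based positions)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["replicon", "position", "depth"],
        header=None,
        dtype={"replicon": str},
    )
    # tolerate a header row
    if len(df) and not str(df.iloc[0]["depth"]).lstrip("-").replace(".", "", 1).isdigit():
        df = df.iloc[1:]
    df["depth"] = df["depth"].astype(float)
    out = {}
    for rep, sub in df.groupby("replicon", sort=False):
        out[rep] = DepthProfile(
            replicon=rep, mean_depth=float(sub["depth"].mean()), n_positions=len(sub)
        )
    return out


def extract_orfs(record: SeqRecord) -> list[tuple[str, int, int, str, Seq]]:
    """Extract coding sequences from an annotated record, strand-aware.

    Returns (id, start, end, strand, coding sequence) with 1-based
    inclusive coordinates.  Minus-strand features are reverse-complemented
    and compound locations (circular wrap-around joins) are concatenated
    in translation order by Biopython's extractor.
    """
    n = len(record.seq)
    out = []
    for idx, feat in enumerate(record.features):
        if feat.type != "CDS":
            continue
        fid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [None]))[0]
        if fid is None:
            fid = f"CDS_{idx + 1}"
        for part in feat.location.parts:
            if int(part.start) < 0 or int(part.end) > n:
                raise ValueError(
                    f"feature {fid}: coordinates {int(part.start) + 1}..{int(part.end)}"
                    f" outside record of length {n}"
                )
        strand = "-" if feat.location.strand == -1 else "+"
        seq = feat.extract(record.seq)
        out.append((fid, int(feat.location.start) + 1, int(feat.location.end), strand, seq))
    return out


def orf_features(record: SeqRecord, table: CodonUsageTable) -> list[OrfFeature]:
    """Compute per-ORF CAI for every annotated CDS of a record."""
    feats = []
    for fid, start, end, strand, seq in extract_orfs(record):
        value, n_used, n_amb = cai_detail(seq, table)
        n_codons = len(seq) // 3
        if str(seq)[-3:].upper() in STOP_CODONS:
            n_codons -= 1  # stop codon not counted in ORF length
        feats.append(
            OrfFeature(
                id=fid,
                start=start,
                end=end,
                strand=strand,
                length_codons=n_codons,
                cai=value,
                n_ambiguous=n_amb,
            )
        )
    return feats


def plasmid_summary(
    record: SeqRecord,
    table: CodonUsageTable,
    plasmid_depth: Optional[DepthProfile] = None,
    chromosome_depth: Optional[DepthProfile] = None,
) -> dict:
    """Per-plasmid feature summary: size, GC%, mean CAI, copy-number proxy."""
    feats = orf_features(record, table)
    summary = {
        "label": record.id,
        "size_bp": len(record.seq),
        "gc_percent": gc_content(record.seq),
        "n_orfs": len(feats),
        "mean_cai": float(np.mean([f.cai for f in feats])) if feats else float("nan"),
    }
    if plasmid_depth is not None and chromosome_depth is not None:
        summary["copy_number"] = copy_number_proxy(plasmid_depth, chromosome_depth)
    return summary
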