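"""Variant-table analytics for within-host evolution experiments.

Consumes breseq-style variant tables (one row per mutational event per
mouse/strain/day, with class, target gene, population frequency and
supporting-read count) and provides the bespoke downstream computations:

* ancestral false-positive filtering (blacklist of ancestral variants with
  frequency > 0.015 and > 3 supporting reads, plus ancestral consensus-mode
  calls);
* event counting by mutation class, dN/dS as a raw count ratio, selective
  sweep calls (frequency > 95% in a mouse);
* parallelism (same target hit in >= 2 mice) and cross-strain convergence
  (same gene or pathway hit in both strains);
* the genomic rate of mutation accumulation M(t): the sum of detected allele
  frequencies divided by elapsed generations (18 generations per gut day);
* mobile-element presence frequency from coverage ratios (region median over
  flank medians, averaged over the two flanks);
* the horizontal-gene-transfer (HGT) read rule: a variant is a potential HGT
  variant when more than 1% of its overlapping reads match the other
  strain's reference genome with 100% identity.

All coordinates are 0-based half-open; conversion to 1-based happens only at
I/O boundaries of formats that require it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantTable",
    "CoverageProfile",
    "SimpleRead",
    "ReadAssignment",
    "RateResult",
    "GENS_PER_DAY",
    "elapsed_generations",
    "filter_ancestral_false_positives",
    "count_events",
    "dn_ds",
    "find_sweeps",
    "parallel_targets",
    "convergent_targets",
    "mutation_rate",
    "element_presence_frequency",
    "classify_hgt_variant",
    "hgt_tract_extent",
    "round_half_away",
]

GENS_PER_DAY = 18

VARIANT_CLASSES = (
    "SNP_NS",
    "SNP_S",
    "SNP_intergenic",
    "IS_insertion",
    "small_indel",
    "large_deletion",
    "HGT",
)

VARIANT_COLUMNS = (
    "strain",
    "mouse",
    "day",
    "contig",
    "position",
    "target",
    "var_class",
    "frequency",
    "supporting_reads",
    "region_start",
    "region_end",
)

ANCESTRAL_FREQ_CUTOFF = 0.015  # strict: frequency must be ABOVE this
ANCESTRAL_READ_CUTOFF = 3  # strict: MORE THAN three supporting reads
SWEEP_THRESHOLD = 0.95
HGT_READ_FRACTION = 0.01


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report convention; banker's rounding off)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class VariantTable:
    """Thin wrapper over a pandas DataFrame in the variant TSV dialect."""

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        for col in VARIANT_COLUMNS:
            if col not in df.columns:
                if col in ("region_start", "region_end"):
                    df[col] = np.nan
                elif col in ("contig",):
                    df[col] = "chr"
                else:
                    raise ValueError(f"variant table missing column {col!r}")
        bad_freq = (df["frequency"] < 0) | (df["frequency"] > 1)
        if bad_freq.any():
            raise ValueError("frequencies must lie in [0, 1]")
        if (df["supporting_reads"] < 0).any():
            raise ValueError("supporting_reads must be >= 0")
        span_classes = df["var_class"].isin(["large_deletion", "HGT"])
        if (span_classes & df["region_start"].isna()).any():
            raise ValueError("large_deletion/HGT records require region_span")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "VariantTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


@dataclass
class CoverageProfile:
    """Per-base depth over one contig plus the element region of interest.

    ``depths[i]`` is the depth at ``start + i`` (0-based); ``region`` is
    half-open; ``flank_size`` base pairs on each side are the comparison
    windows for presence-frequency estimation.
    """

    contig: str
    start: int
    depths: np.ndarray
    region: tuple[int, int]
    flank_size: int = 5000

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if (self.depths < 0).any():
            raise ValueError("depths must be >= 0")
        r0, r1 = self.region
        if not (self.start <= r0 - self.flank_size and r0 < r1):
            raise ValueError("region/flanks must lie within the profile")
        if r1 + self.flank_size > self.start + len(self.depths):
            raise ValueError("right flank extends past the profile")

    def _slice(self, a: int, b: int) -> np.ndarray:
        return self.depths[a - self.start : b - self.start]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "contig": self.contig,
                "position": np.arange(self.start, self.start + len(self.depths)),
                "depth": self.depths,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, region: tuple[int, int], flank_size: int = 5000):
        df = pd.read_csv(path, sep="\t", comment="#").sort_values("position")
        return cls(
            contig=str(df["contig"].iloc[0]),
            start=int(df["position"].iloc[0]),
            depths=df["depth"].to_numpy(),
            region=region,
            flank_size=flank_size,
        )


@dataclass(frozen=True)
class SimpleRead:
    """A sequencing read with its 0-based alignment start on the shared frame."""

    name: str
    seq: str
    start: int


@dataclass(frozen=True)
class ReadAssignment:
    """Per-variant tally of reads matching each reference exactly."""

    position: int
    n_reads: int
    n_match_donor: int
    n_match_recipient: int
    threshold: float = HGT_READ_FRACTION

    def __post_init__(self) -> None:
        if self.n_match_donor + self.n_match_recipient > self.n_reads:
            raise ValueError("matched reads exceed total reads")

    @property
    def donor_fraction(self) -> float:
        return self.n_match_donor / self.n_reads

    @property
    def flagged(self) -> bool:
        """True when more than ``threshold`` of reads match the donor exactly."""
        return self.donor_fraction > self.threshold


@dataclass(frozen=True)
class RateResult:
    """Mutation-accumulation rate M(t) per mouse plus cross-mouse summary."""

    per_mouse: dict
    generations: int
    mean: float
    sd: float
    genome_size: int | None = None

    @property
    def mean_per_bp(self) -> float | None:
        if self.genome_size is None:
            return None
        return self.mean / self.genome_size


# ---------------------------------------------------------------------------
# generation bookkeeping


def elapsed_generations(days: int, gens_per_day: int = GENS_PER_DAY) -> int:
    """Gut generations elapsed after ``days`` of colonization (default 18/day)."""
    if days < 0:
        raise ValueError("days must be >= 0")
    return days * gens_per_day


# ---------------------------------------------------------------------------
# ancestral false-positive filter


def filter_ancestral_false_positives(
    evolved: VariantTable, ancestral: VariantTable
) -> VariantTable:
    """Remove evolved variants that are false positives already seen in ancestors.

    The blacklist is the union of (a) ancestral variants with frequency
    strictly above 0.015 AND strictly more than 3 supporting reads, and
    (b) all ancestral consensus-mode calls (rows whose optional ``mode``
    column equals "consensus"). Evolved variants are removed on a
    (contig, position[, allele]) match; the ``allele`` column participates
    only when present in both tables.
    """
    anc = ancestral.data
    poly_blacklist = anc[
        (anc["frequency"] > ANCESTRAL_FREQ_CUTOFF)
        & (anc["supporting_reads"] > ANCESTRAL_READ_CUTOFF)
    ]
    if "mode" in anc.columns:
        consensus = anc[anc["mode"] == "consensus"]
        blacklist = pd.concat([poly_blacklist, consensus]).drop_duplicates()
    else:
        blacklist = poly_blacklist
    keys = ["contig", "position"]
    if "allele" in blacklist.columns and "allele" in evolved.data.columns:
        keys.append("allele")
    black_keys = set(map(tuple, blacklist[keys].itertuples(index=False, name=None)))
    ev = evolved.data
    mask = [
        tuple(row) not in black_keys
        for row in ev[keys].itertuples(index=False, name=None)
    ]
    return VariantTable(ev[mask])


# ---------------------------------------------------------------------------
# event counting / dN/dS / sweeps


def count_events(
    table: VariantTable, n_mice: int | None = None
) -> dict:
    """Per-class event counts, total, and per-mouse mean +/- SD.

    ``n_mice`` sets the denominator for the per-mouse mean (defaults to the
    number of distinct mice in the table); the reported mean is rounded half
    away from zero to one decimal, matching report conventions.
    """
    df = table.data
    by_class = df["var_class"].value_counts().to_dict()
    total = int(len(df))
    per_mouse = df.groupby("mouse").size() if total else pd.Series(dtype=int)
    if n_mice is None:
        n_mice = int(df["mouse"].nunique())
    counts = np.zeros(max(n_mice, len(per_mouse)))
    counts[: len(per_mouse)] = per_mouse.to_numpy()
    if n_mice > 0:
        mean = total / n_mice
        sd = float(np.std(counts[:n_mice], ddof=1)) if n_mice > 1 else 0.0
    else:
        mean, sd = 0.0, 0.0
    return {
        "by_class": {c: int(by_class.get(c, 0)) for c in VARIANT_CLASSES},
        "total": total,
        "n_mice": n_mice,
        "mean_per_mouse": round_half_away(mean, 1) if n_mice else 0.0,
        "sd_per_mouse": sd,
        "per_mouse": per_mouse.to_dict(),
    }


def dn_ds(table: VariantTable) -> tuple[float, bool]:
    """Raw count ratio of non-synonymous to synonymous SNPs.

    Returns (ratio, defined). With zero synonymous SNPs the ratio is
    undefined: (nan, False) -- reported as "NS>0, S=0" downstream.
    """
    df = table.data
    ns = int((df["var_class"] == "SNP_NS").sum())
    s = int((df["var_class"] == "SNP_S").sum())
    if s == 0:
        return math.nan, False
    return ns / s, True


def find_sweeps(
    table: VariantTable, threshold: float = SWEEP_THRESHOLD
) -> pd.DataFrame:
    """Variants above the sweep frequency threshold, grouped by mouse.

    Strict inequality (frequency > threshold); frequency exactly 1.0 is
    additionally flagged ``fixed``.
    """
    df = table.data
    hits = df[df["frequency"] > threshold].copy()
    hits["fixed"] = hits["frequency"] >= 1.0
    return hits.sort_values(["mouse", "position"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# parallelism and convergence


def _mutation_key(row) -> tuple:
    # identical change: same site, class and (if recorded) allele
    return (row.get("contig", "chr"), row["position"], row["var_class"], row.get("allele"))


def parallel_targets(table: VariantTable) -> pd.DataFrame:
    """Targets mutated in >= 2 mice, split by parallelism level.

    Gene-level: any mutational event in the same target in different mice.
    Mutation-level: the identical change (site + class + allele when
    recorded) in different mice. Rows ordered by descending mouse count then
    target name.
    """
    df = table.data
    if df["mouse"].nunique() < 2:
        raise ValueError("parallelism requires variants from >= 2 mice")
    rows = []
    for target, sub in df.groupby("target"):
        mice = sorted(sub["mouse"].unique())
        if len(mice) < 2:
            continue
        mut_level = False
        for _, mut_sub in sub.groupby(
            sub.apply(lambda r: _mutation_key(r), axis=1)
        ):
            if mut_sub["mouse"].nunique() >= 2:
                mut_level = True
                break
        rows.append(
            {
                "target": target,
                "n_mice": len(mice),
                "mice": ",".join(map(str, mice)),
                "level": "mutation" if mut_level else "gene",
            }
        )
    out = pd.DataFrame(rows, columns=["target", "n_mice", "mice", "level"])
    return out.sort_values(
        ["n_mice", "target"], ascending=[False, True]
    ).reset_index(drop=True)


def convergent_targets(
    table_A: VariantTable,
    table_B1: VariantTable,
    pathway_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Genes or pathways mutated in both strains (cross-strain convergence).

    Gene-level hits are exact target-name intersections; pathway-level hits
    map each target through ``pathway_map`` and intersect the pathways.
    ``same_mouse`` marks convergent targets hit in at least one common mouse.
    """
    pathway_map = pathway_map or {}
    a, b = table_A.data, table_B1.data
    rows = []
    for gene in sorted(set(a["target"]) & set(b["target"])):
        mice_a = set(a.loc[a["target"] == gene, "mouse"])
        mice_b = set(b.loc[b["target"] == gene, "mouse"])
        rows.append(
            {
                "name": gene,
                "level": "gene",
                "targets_A": gene,
                "targets_B1": gene,
                "same_mouse": bool(mice_a & mice_b),
            }
        )
    if pathway_map:
        path_a = {}
        path_b = {}
        for df, bucket in ((a, path_a), (b, path_b)):
            for _, row in df.iterrows():
                pw = pathway_map.get(row["target"])
                if pw is not None:
                    bucket.setdefault(pw, {"targets": set(), "mice": set()})
                    bucket[pw]["targets"].add(row["target"])
                    bucket[pw]["mice"].add(row["mouse"])
        gene_hits = {r["name"] for r in rows}
        for pw in sorted(set(path_a) & set(path_b)):
            # skip pathways whose convergence is already a pure gene-level hit
            if (
                path_a[pw]["targets"] == path_b[pw]["targets"]
                and path_a[pw]["targets"] <= gene_hits
            ):
                continue
            rows.append(
                {
                    "name": pw,
                    "level": "pathway",
                    "targets_A": ",".join(sorted(path_a[pw]["targets"])),
                    "targets_B1": ",".join(sorted(path_b[pw]["targets"])),
                    "same_mouse": bool(path_a[pw]["mice"] & path_b[pw]["mice"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["name", "level", "targets_A", "targets_B1", "same_mouse"]
    )


# ---------------------------------------------------------------------------
# mutation-accumulation rate M(t)


def mutation_rate(
    table: VariantTable,
    generations: int,
    n_mice: int | None = None,
    genome_size: int | None = None,
) -> RateResult:
    """M(t): summed allele frequencies per mouse divided by elapsed generations.

    Mice listed via ``n_mice`` but absent from the table contribute rate 0
    (they were sequenced and showed no retained variants). ``genome_size``
    enables the per-bp normalized variant.
    """
    if generations <= 0:
        raise ValueError("generations must be > 0")
    sums = table.data.groupby("mouse")["frequency"].sum()
    per_mouse = {m: float(s) / generations for m, s in sums.items()}
    if n_mice is not None:
        if n_mice < len(per_mouse):
            raise ValueError("n_mice smaller than number of mice in the table")
        values = list(per_mouse.values()) + [0.0] * (n_mice - len(per_mouse))
    else:
        values = list(per_mouse.values())
    if not values:
        values = [0.0]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return RateResult(
        per_mouse=per_mouse,
        generations=generations,
        mean=mean,
        sd=sd,
        genome_size=genome_size,
    )


# ---------------------------------------------------------------------------
# coverage-ratio element frequency


def element_presence_frequency(cov: CoverageProfile) -> dict:
    """Presence frequency of a genomic element from coverage ratios.

    Computes the ratio of the element-region median depth to each flank's
    median depth and averages the two ratios. Returns the raw value, the
    [0, 1]-clipped reported value, and the complementary deletion/excision
    frequency (1 - presence).
    """
    r0, r1 = cov.region
    left = cov._slice(r0 - cov.flank_size, r0)
    right = cov._slice(r1, r1 + cov.flank_size)
    region = cov._slice(r0, r1)
    med_l, med_r = float(np.median(left)), float(np.median(right))
    if med_l <= 0 or med_r <= 0:
        raise ValueError("flank median depth must be > 0")
    med_region = float(np.median(region))
    raw = 0.5 * (med_region / med_l + med_region / med_r)
    presence = min(max(raw, 0.0), 1.0)
    return {
        "presence_raw": raw,
        "presence": presence,
        "deletion_frequency": 1.0 - presence,
    }


# ---------------------------------------------------------------------------
# HGT read classification


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _matches(read: SimpleRead, ref: str) -> bool:
    ref_sub = ref[read.start : read.start + len(read.seq)]
    if len(ref_sub) != len(read.seq):
        return False
    return read.seq == ref_sub or _revcomp(read.seq) == ref_sub


def classify_hgt_variant(
    reads: Sequence[SimpleRead],
    donor_ref: str,
    recipient_ref: str,
    position: int,
    threshold: float = HGT_READ_FRACTION,
) -> ReadAssignment | None:
    """Apply the HGT read rule at one variant position.

    Considers reads overlapping ``position``; a read matches a reference iff
    it equals the reference substring over its full span exactly (forward or
    reverse complement) -- the stand-in for a 100%-identity alignment. Reads
    matching both references (locally identical sequence) are ambiguous and
    counted for neither. Returns ``None`` (no-call) when no read overlaps.
    The variant is flagged when the donor-matching fraction strictly exceeds
    ``threshold`` (default 1%).
    """
    overlapping = [
        r for r in reads if r.start <= position < r.start + len(r.seq)
    ]
    if not overlapping:
        return None
    n_donor = n_recipient = 0
    for r in overlapping:
        d = _matches(r, donor_ref)
        rec = _matches(r, recipient_ref)
        if d and not rec:
            n_donor += 1
        elif rec and not d:
            n_recipient += 1
    return ReadAssignment(
        position=position,
        n_reads=len(overlapping),
        n_match_donor=n_donor,
        n_match_recipient=n_recipient,
        threshold=threshold,
    )


def hgt_tract_extent(
    flagged_positions: Sequence[int], max_gap: int
) -> list[tuple[int, int]]:
    """Merge flagged variant positions into half-open HGT tracts.

    Positions closer than ``max_gap`` join the same tract; each returned
    tract spans [first, last + 1).
    """
    if not len(flagged_positions):
        return []
    pos = sorted(flagged_positions)
    tracts = []
    start = prev = pos[0]
    for p in pos[1:]:
        if p < prev:
            raise ValueError("positions must be sorted")
        if p - prev > max_gap:
            tracts.append((start, prev + 1))
            start = p
        prev = p
    tracts.append((start, prev + 1))
    return tracts
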