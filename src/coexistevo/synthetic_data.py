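"""Seeded synthetic-data generators with machine-readable ground truth.

Every input the analysis pipeline consumes can be generated here under the
study conditions: two strains at distinct abundances (10^8.5 vs 10^7.4
CFU/g), a ~300 CFU/g plating detection limit, four neutral marker lineages
started at (0.05, 0.05, 0.45, 0.45) of the joint population, breseq-style
variant tables with controlled parallelism and planted sweeps, coverage
profiles over partially deleted elements, read sets drawn from two diverged
references with a planted horizontally transferred tract, logistic growth
curves, and exponential competitive-index series.

Each generator is deterministic given (config, seed) and returns the data
object together with a truth table (``truth_``-prefixed columns) that
recovery tests consume instead of re-deriving the planted structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitness_assays import CompetitionSeries, GrowthCurve
from .marker_dynamics import STRAIN_MARKERS, MarkerTrajectory
from .simulator import DFEParams, SimParams, run_replicate
from .variant_analysis import (
    VARIANT_COLUMNS,
    CoverageProfile,
    SimpleRead,
    VariantTable,
)

__all__ = [
    "SynthConfig",
    "gen_marker_trajectories",
    "gen_variant_tables",
    "gen_coverage",
    "gen_reads",
    "gen_growth",
    "gen_competition",
    "reads_to_fasta",
    "reads_from_fasta",
    "references_to_fasta",
]

#: sampling days emulating a three-month colonization with frequent early plating
DEFAULT_DAYS = (1, 4, 7, 11, 15, 22, 29, 36, 43, 57, 71, 88)

# per-class event mixes follow the observed breakdowns: 82 strain-B1 events
# split 34/4/16 SNS/S/intergenic SNPs + 8 IS + 9 indels + 11 large deletions,
# and 38 strain-A events split 10/2/1 + 11 + 5 + 9.
CLASS_MIX_B1 = {
    "SNP_NS": 34 / 82,
    "SNP_S": 4 / 82,
    "SNP_intergenic": 16 / 82,
    "IS_insertion": 8 / 82,
    "small_indel": 9 / 82,
    "large_deletion": 11 / 82,
}
CLASS_MIX_A = {
    "SNP_NS": 10 / 38,
    "SNP_S": 2 / 38,
    "SNP_intergenic": 1 / 38,
    "IS_insertion": 11 / 38,
    "small_indel": 5 / 38,
    "large_deletion": 9 / 38,
}

PARALLEL_POOL = {
    "A": ("frlR", "fimE", "focA/ycaO", "mngB/cydA", "e14"),
    "B1": ("fimH", "yadA", "dpiB", "tdcA", "ydaA", "bigdel1", "bigdel2"),
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of all generators; defaults are the study conditions."""

    n_mice: int = 8
    days: tuple[int, ...] = DEFAULT_DAYS
    detection_limit: float = 300.0
    # strain loads, log10 CFU/g
    load_log10_mean_A: float = 7.4
    load_log10_mean_B1: float = 8.5
    load_log10_sd: float = 0.4
    initial_fractions: tuple[float, float, float, float] = (0.05, 0.05, 0.45, 0.45)
    # trajectory truth pattern (parametric mode): which strains lose a marker
    loss_day_A: int = 43
    fraction_mice_losing_A: float = 1.0
    fraction_mice_losing_B1: float = 0.0
    # simulator-backed trajectory mode
    sim_n_total: int = 10**6
    sim_u: float = 1e-5
    sim_mean_s: float = 0.01
    sim_dfe_kind: str = "fixed"
    sim_dfe_shape: float | None = None
    # variant tables
    mean_events_A: float = 38 / 8
    mean_events_B1: float = 82 / 8
    parallelism_fraction: float = 0.3
    sweep_fraction_A: float = 9 / 38
    sweep_fraction_B1: float = 0.0
    genome_size_A: int = 4_500_000
    genome_size_B1: int = 5_200_000
    # coverage
    coverage_depth: float = 100.0
    coverage_region: tuple[int, int] = (20_000, 30_000)
    coverage_flank: int = 5_000
    # reads / references
    genome_length: int = 40_000
    divergence: float = 0.02
    read_length: int = 100
    read_depth: float = 100.0
    read_error_rate: float = 0.0
    hgt_tract: tuple[int, int] = (10_000, 30_000)
    donor_fraction: float = 0.5
    # growth curves (defaults on the resident-strain ancestor scale)
    growth_r: float = 1.08
    growth_K: float = 0.8
    growth_x0: float = 8e-4
    growth_blank: float = 0.04
    growth_noise_sd: float = 0.003
    growth_hours: float = 24.0
    growth_interval_h: float = 1 / 6  # a reading every 10 minutes
    # competition
    comp_n_mice: int = 4
    comp_days: tuple[int, ...] = (0, 1, 2, 3, 4)
    comp_s_per_day: float = 4.0
    comp_log_noise_sd: float = 0.0
    comp_start_cfu: float = 1e7


# ---------------------------------------------------------------------------
# marker trajectories


def _emit_cfu(rng, log10_mean: float, sd: float) -> float:
    return 10 ** (log10_mean + (rng.normal(0.0, sd) if sd > 0 else 0.0))


def gen_marker_trajectories(
    cfg: SynthConfig, seed: int = 0, mode: str = "parametric"
) -> tuple[MarkerTrajectory, pd.DataFrame]:
    """CFU trajectories of the four markers plus a per-(mouse, strain) truth table.

    ``parametric`` mode plants the experimental pattern directly: in a
    configured fraction of mice, strain A's second marker drops to zero from
    ``loss_day_A`` on, while strain B1 keeps a fluctuating two-marker split.
    ``from_simulator`` mode takes within-strain marker frequencies from
    Wright-Fisher replicates (one per mouse, 18 generations per day) and
    multiplies them by lognormal strain loads. Counts below the detection
    limit are emitted as 0.
    """
    if mode not in ("parametric", "from_simulator"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    lod = cfg.detection_limit
    rows, truth_rows = [], []
    for mouse in range(1, cfg.n_mice + 1):
        if mode == "from_simulator":
            params = SimParams(
                n_total=cfg.sim_n_total,
                generations=max(cfg.days) * 18,
                u=cfg.sim_u,
                dfe=(
                    DFEParams(kind="fixed", mean_s=cfg.sim_mean_s)
                    if cfg.sim_dfe_kind == "fixed"
                    else DFEParams(
                        kind="gamma", mean_s=cfg.sim_mean_s, shape=cfg.sim_dfe_shape
                    )
                ),
                initial_fractions=cfg.initial_fractions,
                seed=seed * 1000 + mouse,
                record_every=18,
            )
            result = run_replicate(params)
            snap_of_day = {
                int(g) // 18: i
                for i, g in enumerate(result.snapshot_generations)
                if g % 18 == 0
            }
        lose_A = rng.random() < cfg.fraction_mice_losing_A
        lose_B1 = rng.random() < cfg.fraction_mice_losing_B1
        b1_split = 0.5
        true_cfu_by_day = {}
        for day in cfg.days:
            load_A = _emit_cfu(rng, cfg.load_log10_mean_A, cfg.load_log10_sd)
            load_B1 = _emit_cfu(rng, cfg.load_log10_mean_B1, cfg.load_log10_sd)
            if mode == "from_simulator":
                within = result.within_strain_marker_freq[snap_of_day[day]]
                fA = within[0]
                fB = within[1]
                if np.isnan(fA).any():
                    fA = np.array([0.0, 0.0])
                    load_A = 0.0
                if np.isnan(fB).any():
                    fB = np.array([0.0, 0.0])
                    load_B1 = 0.0
            else:
                if lose_A and day >= cfg.loss_day_A:
                    fA = np.array([1.0, 0.0])
                else:
                    fA = np.array([0.5, 0.5])
                b1_split = float(np.clip(b1_split + rng.normal(0, 0.05), 0.15, 0.85))
                if lose_B1 and day >= cfg.loss_day_A:
                    fB = np.array([1.0, 0.0])
                else:
                    fB = np.array([b1_split, 1.0 - b1_split])
            true_cfu = {}
            for strain, load, f in (("A", load_A, fA), ("B1", load_B1, fB)):
                for m_idx, marker in enumerate(STRAIN_MARKERS[strain]):
                    cfu = load * float(f[m_idx])
                    true_cfu[marker] = cfu
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "day": day,
                            "marker": marker,
                            "cfu_per_g": cfu if cfu >= lod else 0.0,
                        }
                    )
            true_cfu_by_day[day] = true_cfu
        # ground truth: the marker-loss call rules applied to the
        # pre-detection-limit values (below-LOD on the last 2 sampled days;
        # not-colonized = strain absent from day 7 onward)
        days_sorted = sorted(cfg.days)
        last2 = days_sorted[-2:]
        for strain in ("A", "B1"):
            markers = STRAIN_MARKERS[strain]
            absent = {
                d: all(true_cfu_by_day[d][m] < lod for m in markers)
                for d in days_sorted
            }
            late = [d for d in days_sorted if d >= 7]
            below = [
                all(true_cfu_by_day[d][m] < lod and not absent[d] for d in last2)
                for m in markers
            ]
            if late and all(absent[d] for d in late):
                status = "strain_not_colonized"
                fixed = ""
            elif sum(below) == 1:
                status = "lost"
                fixed = markers[0] if below[1] else markers[1]
            else:
                status = "maintained"
                fixed = ""
            truth_rows.append(
                {
                    "truth_mouse_id": mouse,
                    "truth_strain": strain,
                    "truth_status": status,
                    "truth_fixed_marker": fixed,
                }
            )
    traj = MarkerTrajectory(
        data=pd.DataFrame(rows), detection_limit=cfg.detection_limit
    )
    return traj, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# variant tables


def gen_variant_tables(
    cfg: SynthConfig, seed: int = 0, strain: str = "B1", day: int = 88
) -> tuple[VariantTable, dict]:
    """Variant table for one strain with planted parallelism and sweeps.

    Per mouse the event count is Poisson around the configured mean; each
    event picks its class from the strain's observed class mix. With
    probability ``parallelism_fraction`` the event hits a target from a
    small shared pool (re-used across mice, generating parallelism),
    otherwise a mouse-private target. With probability ``sweep_fraction``
    the frequency is drawn above the 95% sweep threshold.

    Truth lists parallel targets, per-mouse frequency sums and planted
    sweep counts.
    """
    if strain not in ("A", "B1"):
        raise ValueError("strain must be 'A' or 'B1'")
    rng = np.random.default_rng(seed)
    mean_events = cfg.mean_events_A if strain == "A" else cfg.mean_events_B1
    mix = CLASS_MIX_A if strain == "A" else CLASS_MIX_B1
    sweep_frac = cfg.sweep_fraction_A if strain == "A" else cfg.sweep_fraction_B1
    genome = cfg.genome_size_A if strain == "A" else cfg.genome_size_B1
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    pool = PARALLEL_POOL[strain]
    rows = []
    target_mice: dict[str, set] = {}
    freq_sums: dict[int, float] = {}
    n_sweeps = 0
    for mouse in range(1, cfg.n_mice + 1):
        n_events = rng.poisson(mean_events)
        freq_sums[mouse] = 0.0
        for i in range(n_events):
            var_class = classes[rng.choice(len(classes), p=probs)]
            if rng.random() < cfg.parallelism_fraction:
                target = pool[rng.integers(len(pool))]
            else:
                target = f"gene_m{mouse}_{i}"
            if rng.random() < sweep_frac:
                freq = float(rng.uniform(0.96, 1.0))
                n_sweeps += 1
            else:
                freq = float(rng.uniform(0.02, 0.9))
            position = int(rng.integers(0, genome))
            span = var_class in ("large_deletion", "HGT")
            rows.append(
                {
                    "strain": strain,
                    "mouse": mouse,
                    "day": day,
                    "contig": "chr",
                    "position": position,
                    "target": target,
                    "var_class": var_class,
                    "frequency": freq,
                    "supporting_reads": int(rng.poisson(freq * 100) + 5),
                    "region_start": position if span else np.nan,
                    "region_end": position + int(rng.integers(5_000, 90_000))
                    if span
                    else np.nan,
                }
            )
            target_mice.setdefault(target, set()).add(mouse)
            freq_sums[mouse] += freq
    table = VariantTable(pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)))
    truth = {
        "parallel_targets": sorted(
            t for t, mice in target_mice.items() if len(mice) >= 2
        ),
        "freq_sums": freq_sums,
        "n_sweeps": n_sweeps,
        "n_events": len(rows),
    }
    return table, truth


# ---------------------------------------------------------------------------
# coverage profiles


def gen_coverage(
    cfg: SynthConfig, presence_p: float, seed: int = 0
) -> tuple[CoverageProfile, dict]:
    """Poisson coverage over an element present in a fraction ``presence_p`` of cells.

    Flank depths are Poisson(depth); depths inside the element region are
    Poisson(depth * presence_p), emulating a partial deletion/excision.
    """
    if not 0.0 <= presence_p <= 1.0:
        raise ValueError("presence_p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    r0, r1 = cfg.coverage_region
    start = r0 - cfg.coverage_flank
    n = (r1 + cfg.coverage_flank) - start
    depths = rng.poisson(cfg.coverage_depth, size=n).astype(float)
    region_slice = slice(r0 - start, r1 - start)
    depths[region_slice] = rng.poisson(
        cfg.coverage_depth * presence_p, size=r1 - r0
    )
    profile = CoverageProfile(
        contig="chr",
        start=start,
        depths=depths,
        region=cfg.coverage_region,
        flank_size=cfg.coverage_flank,
    )
    return profile, {"truth_presence": presence_p, "truth_depth": cfg.coverage_depth}


# ---------------------------------------------------------------------------
# reads and references with a planted HGT tract

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_genome(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def gen_reads(
    cfg: SynthConfig, seed: int = 0
) -> tuple[list[SimpleRead], str, str, pd.DataFrame]:
    """Read set over two diverged references with a planted donor tract.

    The recipient genome is random sequence; the donor differs at SNP
    density ``divergence`` (colinear, same coordinate frame). Reads are
    drawn uniformly along the recipient; a read falling entirely inside the
    planted tract originates from the donor with probability
    ``donor_fraction``. Returns (reads, donor_seq, recipient_seq, truth);
    truth has one row per read (origin and tract bounds) plus the diverged
    site positions are recoverable as positions where the references differ.
    """
    if not cfg.divergence > 0:
        raise ValueError("divergence must be > 0 so references are distinguishable")
    rng = np.random.default_rng(seed)
    L, rl = cfg.genome_length, cfg.read_length
    t0, t1 = cfg.hgt_tract
    recipient = _random_genome(rng, L)
    donor = recipient.copy()
    snp_sites = np.flatnonzero(rng.random(L) < cfg.divergence)
    donor[snp_sites] = (donor[snp_sites] + rng.integers(1, 4, size=len(snp_sites))) % 4
    n_reads = int(round(cfg.read_depth * L / rl))
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    in_tract = (starts >= t0) & (starts + rl <= t1)
    from_donor = in_tract & (rng.random(n_reads) < cfg.donor_fraction)
    reads, truth_rows = [], []
    recipient_str, donor_str = _to_str(recipient), _to_str(donor)
    for i, (s, d) in enumerate(zip(starts, from_donor)):
        src = donor if d else recipient
        seq = src[s : s + rl].copy()
        if cfg.read_error_rate > 0:
            err = rng.random(rl) < cfg.read_error_rate
            seq[err] = (seq[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        reads.append(SimpleRead(name=f"read{i}", seq=_to_str(seq), start=int(s)))
        truth_rows.append(
            {
                "truth_read": f"read{i}",
                "truth_origin": "donor" if d else "recipient",
                "truth_tract_start": t0,
                "truth_tract_end": t1,
            }
        )
    return reads, donor_str, recipient_str, pd.DataFrame(truth_rows)


def reads_to_fasta(reads, truth: pd.DataFrame, path) -> None:
    """Write reads as FASTA; truth labels go in the description field."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    origin = dict(zip(truth["truth_read"], truth["truth_origin"]))
    t0 = int(truth["truth_tract_start"].iloc[0])
    t1 = int(truth["truth_tract_end"].iloc[0])
    records = [
        SeqRecord(
            Seq(r.seq),
            id=r.name,
            description=f"start={r.start} origin={origin[r.name]} tract={t0}-{t1}",
        )
        for r in reads
    ]
    SeqIO.write(records, path, "fasta")


def reads_from_fasta(path) -> tuple[list[SimpleRead], pd.DataFrame]:
    from Bio import SeqIO

    reads, truth_rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        fields = dict(
            kv.split("=") for kv in rec.description.split() if "=" in kv
        )
        reads.append(
            SimpleRead(name=rec.id, seq=str(rec.seq), start=int(fields["start"]))
        )
        t0, t1 = fields["tract"].split("-")
        truth_rows.append(
            {
                "truth_read": rec.id,
                "truth_origin": fields["origin"],
                "truth_tract_start": int(t0),
                "truth_tract_end": int(t1),
            }
        )
    return reads, pd.DataFrame(truth_rows)


def references_to_fasta(donor: str, recipient: str, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [
            SeqRecord(Seq(donor), id="donor", description="synthetic donor reference"),
            SeqRecord(
                Seq(recipient), id="recipient", description="synthetic recipient reference"
            ),
        ],
        path,
        "fasta",
    )


# ---------------------------------------------------------------------------
# growth curves and competitions


def gen_growth(cfg: SynthConfig, seed: int = 0, label: str = "clone") -> tuple[GrowthCurve, dict]:
    """Logistic OD curve plus Gaussian read noise; truth carries (r, K)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, cfg.growth_hours + 1e-9, cfg.growth_interval_h)
    K, x0, r = cfg.growth_K, cfg.growth_x0, cfg.growth_r
    od = cfg.growth_blank + K / (1.0 + ((K - x0) / x0) * np.exp(-r * t))
    if cfg.growth_noise_sd > 0:
        od = od + rng.normal(0.0, cfg.growth_noise_sd, size=len(t))
    od = np.clip(od, 0.0, None)
    curve = GrowthCurve(times=t, od=od, blank=cfg.growth_blank, label=label)
    return curve, {"truth_r": r, "truth_K": K, "truth_x0": x0}


def gen_competition(cfg: SynthConfig, seed: int = 0) -> tuple[CompetitionSeries, dict]:
    """Competitive-index series: ln(focal/reference) rises at s per day."""
    rng = np.random.default_rng(seed)
    rows = []
    for mouse in range(1, cfg.comp_n_mice + 1):
        for day in cfg.comp_days:
            noise_f = (
                math.exp(rng.normal(0.0, cfg.comp_log_noise_sd))
                if cfg.comp_log_noise_sd > 0
                else 1.0
            )
            noise_r = (
                math.exp(rng.normal(0.0, cfg.comp_log_noise_sd))
                if cfg.comp_log_noise_sd > 0
                else 1.0
            )
            rows.append(
                {
                    "mouse_id": mouse,
                    "day": day,
                    "cfu_focal": cfg.comp_start_cfu
                    * math.exp(cfg.comp_s_per_day * day)
                    * noise_f,
                    "cfu_reference": cfg.comp_start_cfu * noise_r,
                }
            )
    series = CompetitionSeries(data=pd.DataFrame(rows))
    return series, {"truth_s_per_day": cfg.comp_s_per_day}
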