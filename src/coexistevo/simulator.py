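"""Wright-Fisher simulation of two barcoded strains under clonal evolution.

Two bacterial strains (A and B1) co-colonize a host gut at a constant joint
census size N. Each strain carries two neutral fluorescent markers, giving
four founder lineages. Beneficial mutations arise at per-individual rate u
per generation with selective advantages drawn from a distribution of
fitness effects (DFE); each generation the whole population is resampled
multinomially with probabilities proportional to lineage count x fitness.
Because the markers are neutral, their frequency dynamics read out the
underlying sweep dynamics: a hard selective sweep drags one marker to
fixation (hitchhiking), while clonal interference preserves marker
polymorphism.

The population is stored as an exact lineage ledger (marker id, fitness,
count) so continuous gamma-distributed effects are represented without
binning. Census conservation is exact at every generation.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DFEParams",
    "SimParams",
    "PopulationState",
    "SimResult",
    "OutcomePattern",
    "STRAIN_OF_MARKER",
    "STRAIN_NAMES",
    "make_population",
    "sample_effects",
    "advance_generation",
    "run_replicate",
    "classify_outcome",
]

#: marker id -> strain index (0 = A, 1 = B1); markers 0,1 belong to the
#: low-abundance strain A, markers 2,3 to the resident strain B1.
STRAIN_OF_MARKER = (0, 0, 1, 1)
STRAIN_NAMES = ("A", "B1")

#: default within-strain frequency below which a marker is called lost
DEFAULT_LOSS_THRESHOLD = 1e-3
#: default total-population frequency below which a strain is called extinct
DEFAULT_EXTINCTION_THRESHOLD = 1e-2


class ValidationError(ValueError):
    """Raised when simulation parameters violate their invariants."""


@dataclass(frozen=True)
class DFEParams:
    """Distribution of fitness effects of newly arising beneficial mutations.

    Parameters
    ----------
    kind:
        ``"fixed"`` (every mutation has effect exactly ``mean_s``) or
        ``"gamma"`` (effects ~ Gamma(shape, scale=mean_s/shape), so the
        distribution mean is ``mean_s``). ``fixed`` is the shape -> infinity
        limit of the gamma family; shape 1 is the exponential DFE.
    mean_s:
        Mean selective advantage per mutation (dimensionless, > 0).
    shape:
        Gamma shape parameter (> 0); ignored for ``kind="fixed"``.
    """

    kind: str
    mean_s: float
    shape: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "gamma"):
            raise ValidationError(f"unknown DFE kind {self.kind!r}")
        if not self.mean_s > 0:
            raise ValidationError("mean_s must be > 0")
        if self.kind == "gamma":
            if self.shape is None or not self.shape > 0:
                raise ValidationError("gamma DFE requires shape > 0")


@dataclass(frozen=True)
class SimParams:
    """Parameters of one Wright-Fisher replicate.

    ``initial_fractions`` is ordered (A-marker0, A-marker1, B1-marker0,
    B1-marker1) and must sum to 1. ``record_every`` sets the snapshot
    spacing in generations (default 18 = one day of gut colonization).
    """

    n_total: int
    generations: int
    u: float
    dfe: DFEParams
    initial_fractions: tuple[float, float, float, float] = (0.05, 0.05, 0.45, 0.45)
    seed: int = 0
    record_every: int = 18

    def __post_init__(self) -> None:
        if self.n_total < 4:
            raise ValidationError("n_total must be >= 4")
        if not (0.0 <= self.u <= 1.0):
            raise ValidationError("u must lie in [0, 1]")
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if len(self.initial_fractions) != 4:
            raise ValidationError("initial_fractions must have length 4")
        if any(f < 0 for f in self.initial_fractions):
            raise ValidationError("initial_fractions must be non-negative")
        if abs(sum(self.initial_fractions) - 1.0) > 1e-12:
            raise ValidationError("initial_fractions must sum to 1 within 1e-12")
        if self.record_every < 1:
            raise ValidationError("record_every must be >= 1")


@dataclass
class PopulationState:
    """Exact lineage ledger: parallel arrays of (marker, fitness, count).

    Zero-count lineages are pruned; the count column always sums to the
    census size. ``mutations_arisen`` accumulates the number of mutation
    events since generation 0.
    """

    marker: np.ndarray
    fitness: np.ndarray
    count: np.ndarray
    generation: int = 0
    mutations_arisen: int = 0

    @property
    def n_total(self) -> int:
        return int(self.count.sum())

    def marker_frequencies(self) -> np.ndarray:
        """Frequencies of the four markers in the total population."""
        n = self.n_total
        freqs = np.zeros(4)
        np.add.at(freqs, self.marker, self.count)
        return freqs / n

    def strain_frequencies(self) -> np.ndarray:
        """Frequencies of strain A and strain B1 in the total population."""
        mf = self.marker_frequencies()
        return np.array([mf[0] + mf[1], mf[2] + mf[3]])

    def within_strain_frequencies(self) -> np.ndarray:
        """Per-strain 2-vectors of marker frequencies; NaN if strain extinct."""
        mf = self.marker_frequencies()
        out = np.full((2, 2), np.nan)
        for strain in (0, 1):
            pair = mf[2 * strain : 2 * strain + 2]
            tot = pair.sum()
            if tot > 0:
                out[strain] = pair / tot
        return out


@dataclass
class SimResult:
    """Trajectory snapshots and final state of one replicate."""

    params: SimParams
    snapshot_generations: np.ndarray  # (S,)
    marker_freq_trajectory: np.ndarray  # (S, 4), each row sums to 1
    within_strain_marker_freq: np.ndarray  # (S, 2, 2), NaN when strain extinct
    n_mutations_arisen: int
    final_state: PopulationState

    @property
    def seed(self) -> int:
        return self.params.seed

    def to_tsv(self, path_or_buf) -> None:
        """Serialize snapshots as TSV with a ``#``-prefixed metadata header."""
        dfe = self.params.dfe
        meta = {
            "n_total": self.params.n_total,
            "generations": self.params.generations,
            "u": self.params.u,
            "dfe_kind": dfe.kind,
            "dfe_mean_s": dfe.mean_s,
            "dfe_shape": "" if dfe.shape is None else dfe.shape,
            "initial_fractions": ",".join(map(repr, self.params.initial_fractions)),
            "seed": self.params.seed,
            "record_every": self.params.record_every,
            "n_mutations_arisen": self.n_mutations_arisen,
        }
        lines = [f"# {k}={v}" for k, v in meta.items()]
        lines.append(
            "generation\tmarker_id\tstrain\tcount\tfrequency\t"
            "within_strain_frequency"
        )
        for i, g in enumerate(self.snapshot_generations):
            for m in range(4):
                strain = STRAIN_NAMES[STRAIN_OF_MARKER[m]]
                freq = float(self.marker_freq_trajectory[i, m])
                count = round(freq * self.params.n_total)
                wf = self.within_strain_marker_freq[i, STRAIN_OF_MARKER[m], m % 2]
                wf_str = "" if np.isnan(wf) else repr(float(wf))
                lines.append(
                    f"{int(g)}\t{m}\t{strain}\t{count}\t{freq!r}\t{wf_str}"
                )
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def read_tsv(cls, path_or_buf) -> "SimResult":
        """Round-trip reader for :meth:`to_tsv` output.

        The final lineage ledger is not serialized; ``final_state`` of the
        returned object holds only the last snapshot's marker counts.
        """
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta: dict[str, str] = {}
        rows = []
        for line in text.splitlines():
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
            elif line and not line.startswith("generation\t"):
                rows.append(line.split("\t"))
        shape = meta["dfe_shape"]
        dfe = DFEParams(
            kind=meta["dfe_kind"],
            mean_s=float(meta["dfe_mean_s"]),
            shape=float(shape) if shape else None,
        )
        params = SimParams(
            n_total=int(meta["n_total"]),
            generations=int(meta["generations"]),
            u=float(meta["u"]),
            dfe=dfe,
            initial_fractions=tuple(
                float(x) for x in meta["initial_fractions"].split(",")
            ),
            seed=int(meta["seed"]),
            record_every=int(meta["record_every"]),
        )
        gens = sorted({int(r[0]) for r in rows})
        gen_index = {g: i for i, g in enumerate(gens)}
        traj = np.zeros((len(gens), 4))
        within = np.full((len(gens), 2, 2), np.nan)
        for g, m, _strain, _count, freq, wf in rows:
            i, m = gen_index[int(g)], int(m)
            traj[i, m] = float(freq)
            if wf != "":
                within[i, STRAIN_OF_MARKER[m], m % 2] = float(wf)
        counts = np.rint(traj[-1] * params.n_total).astype(np.int64)
        final = PopulationState(
            marker=np.arange(4)[counts > 0],
            fitness=np.ones(int((counts > 0).sum())),
            count=counts[counts > 0],
            generation=gens[-1],
        )
        return cls(
            params=params,
            snapshot_generations=np.asarray(gens),
            marker_freq_trajectory=traj,
            within_strain_marker_freq=within,
            n_mutations_arisen=int(meta["n_mutations_arisen"]),
            final_state=final,
        )


@dataclass(frozen=True)
class OutcomePattern:
    """Marker-maintenance pattern of a finished replicate.

    ``compatible`` is True when the replicate reproduces the experimental
    pattern: both strains extant, the low-abundance strain A keeping exactly
    one marker and the resident strain B1 keeping both.
    """

    markers_maintained_A: int
    markers_maintained_B1: int
    strain_A_extant: bool
    strain_B1_extant: bool

    @property
    def compatible(self) -> bool:
        return (
            self.strain_A_extant
            and self.strain_B1_extant
            and self.markers_maintained_A == 1
            and self.markers_maintained_B1 == 2
        )


def _largest_remainder(fractions: np.ndarray, n_total: int) -> np.ndarray:
    """Integer apportionment: floors plus leftovers to the largest remainders."""
    raw = fractions * n_total
    base = np.floor(raw).astype(np.int64)
    leftover = n_total - int(base.sum())
    if leftover:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:leftover]] += 1
    return base


def make_population(params: SimParams) -> PopulationState:
    """Seed the four founder lineages, all at fitness exactly 1.

    Counts are largest-remainder roundings of fraction x n_total and sum
    exactly to ``n_total``. A positive fraction that rounds to zero emits a
    warning and the lineage is pruned.
    """
    fractions = np.asarray(params.initial_fractions, dtype=float)
    counts = _largest_remainder(fractions, params.n_total)
    zeroed = (counts == 0) & (fractions > 0)
    if zeroed.any():
        warnings.warn(
            f"founder fractions {fractions[zeroed]} round to zero individuals "
            f"at n_total={params.n_total}",
            stacklevel=2,
        )
    keep = counts > 0
    return PopulationState(
        marker=np.arange(4, dtype=np.int64)[keep],
        fitness=np.ones(int(keep.sum())),
        count=counts[keep],
        generation=0,
    )


def sample_effects(
    n_draws: int, dfe: DFEParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw selective advantages for ``n_draws`` new mutations."""
    if n_draws < 0:
        raise ValidationError("n_draws must be >= 0")
    if dfe.kind == "fixed":
        return np.full(n_draws, dfe.mean_s)
    return rng.gamma(shape=dfe.shape, scale=dfe.mean_s / dfe.shape, size=n_draws)


def advance_generation(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> PopulationState:
    """One Wright-Fisher generation: mutation first, then multinomial resampling.

    Each lineage yields Binomial(count, u) mutants; every mutant founds a new
    lineage with fitness parent x (1 + s), s drawn from the DFE (fitness
    across multiple mutations composes multiplicatively). The next generation
    is then drawn multinomially with probabilities proportional to
    count x fitness. Census size is conserved exactly; extinct lineages are
    pruned.
    """
    marker, fitness, count = state.marker, state.fitness, state.count
    n_new = 0
    if params.u > 0.0:
        n_mut = rng.binomial(count, params.u)
        n_new = int(n_mut.sum())
        if n_new:
            parent = np.repeat(np.arange(len(count)), n_mut)
            effects = sample_effects(n_new, params.dfe, rng)
            marker = np.concatenate([marker, marker[parent]])
            fitness = np.concatenate([fitness, fitness[parent] * (1.0 + effects)])
            count = np.concatenate([count - n_mut, np.ones(n_new, dtype=np.int64)])
    weights = count * fitness
    total_weight = weights.sum()
    if not total_weight > 0:
        raise RuntimeError("all lineage weights vanished; cannot resample")
    new_count = rng.multinomial(params.n_total, weights / total_weight)
    keep = new_count > 0
    return PopulationState(
        marker=marker[keep],
        fitness=fitness[keep],
        count=new_count[keep].astype(np.int64),
        generation=state.generation + 1,
        mutations_arisen=state.mutations_arisen + n_new,
    )


def run_replicate(params: SimParams) -> SimResult:
    """Run one replicate; same ``(params, seed)`` gives bit-identical output.

    Snapshots are taken at generations 0, record_every, 2*record_every, ...
    and always at the final generation.
    """
    rng = np.random.default_rng(params.seed)
    state = make_population(params)
    snap_gens = [0]
    traj = [state.marker_frequencies()]
    within = [state.within_strain_frequencies()]
    for gen in range(1, params.generations + 1):
        state = advance_generation(state, params, rng)
        if gen % params.record_every == 0 or gen == params.generations:
            snap_gens.append(gen)
            traj.append(state.marker_frequencies())
            within.append(state.within_strain_frequencies())
    return SimResult(
        params=params,
        snapshot_generations=np.asarray(snap_gens),
        marker_freq_trajectory=np.asarray(traj),
        within_strain_marker_freq=np.asarray(within),
        n_mutations_arisen=state.mutations_arisen,
        final_state=state,
    )


def classify_outcome(
    result: SimResult,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
) -> OutcomePattern:
    """Score a finished replicate against the experimental marker pattern.

    A marker is maintained iff its final within-strain frequency is
    >= ``loss_threshold`` (default 0.001; CFU plating cannot resolve rarer
    lineages). A strain is extant iff its final total-population frequency is
    >= ``extinction_threshold`` (default 0.01); the pattern being matched
    requires strain coexistence.
    """
    mf = result.marker_freq_trajectory[-1]
    within = result.within_strain_marker_freq[-1]
    strain_freq = np.array([mf[0] + mf[1], mf[2] + mf[3]])
    extant = strain_freq >= extinction_threshold
    maintained = []
    for strain in (0, 1):
        pair = within[strain]
        if np.isnan(pair).any():
            maintained.append(0)
        else:
            maintained.append(int((pair >= loss_threshold).sum()))
    return OutcomePattern(
        markers_maintained_A=maintained[0],
        markers_maintained_B1=maintained[1],
        strain_A_extant=bool(extant[0]),
        strain_B1_extant=bool(extant[1]),
    )
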