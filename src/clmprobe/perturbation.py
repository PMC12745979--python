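"""Sequence-modification protocols probing what a trained model relies on.

Three protocols are implemented, each producing sequence *variants* that are
fed back through sampling-based evaluation:

* cumulative randomization — starting from the N or C terminus, successive
  15-residue segments are replaced by residues drawn with corpus-frequency
  likelihoods, until the whole sequence is randomized; positional controls
  randomize the same number of residues at fresh random positions per step;
* motif masking — known motif windows (1-based inclusive ranges) are either
  randomized or consistently replaced with alanine; controls modify the same
  number of residues at random positions, re-drawn each trial;
* full randomization — the degenerate end point of the cumulative protocol.

A "targeted" position counts as randomized even when the drawn residue
happens to equal the original (the draw is from the corpus frequency
distribution, which does not exclude the original residue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import PairDataset
from .encoding import IUPAC_AMINO_ACIDS
from .evaluation import count_reproduced
from .model import SequenceToCompoundTransformer

DEFAULT_SEGMENT = 15
CUMULATIVE_REPEATS = 5
MASKING_REPEATS = 10

PERTURBATION_KINDS = (
    "cumulative_n_to_c",
    "cumulative_c_to_n",
    "cumulative_random_control",
    "motif_randomize",
    "motif_alanine",
    "motif_random_control_randomize",
    "motif_random_control_alanine",
    "full_randomization",
)


@dataclass(frozen=True)
class ResidueFrequencies:
    """Relative amino-acid frequencies over a sequence corpus (sums to 1)."""

    frequencies: dict[str, float]

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")
        if any(v < 0 for v in self.frequencies.values()):
            raise ValueError("negative frequency")

    def draw(self, rng: np.random.Generator, size: int) -> list[str]:
        letters = sorted(self.frequencies)
        probs = np.array([self.frequencies[a] for a in letters])
        return [letters[i] for i in rng.choice(len(letters), size=size, p=probs)]


def residue_frequencies(sequences) -> ResidueFrequencies:
    """Frequency of each residue over all positions of all corpus sequences."""
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for ch in seq:
            counts[ch] = counts.get(ch, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("empty corpus")
    return ResidueFrequencies({a: c / total for a, c in counts.items()})


def uniform_frequencies() -> ResidueFrequencies:
    n = len(IUPAC_AMINO_ACIDS)
    return ResidueFrequencies({a: 1.0 / n for a in IUPAC_AMINO_ACIDS})


@dataclass(frozen=True)
class PerturbationPlan:
    """Declarative description of one perturbation experiment."""

    kind: str
    segment: int = DEFAULT_SEGMENT
    motif_ranges: tuple[tuple[int, int], ...] = ()
    repeats: int = CUMULATIVE_REPEATS
    seed: int = 0
    n_samples: int = 5000
    temperature: float = 1.0

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.segment < 1:
            raise ValueError("segment size must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def plan_to_json(plan: PerturbationPlan, path) -> None:
    from dataclasses import asdict
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(asdict(plan), indent=2))


def plan_from_json(path) -> PerturbationPlan:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    d["motif_ranges"] = tuple(tuple(r) for r in d.get("motif_ranges", ()))
    return PerturbationPlan(**d)


def write_variants_fasta(variants: dict[str, str], path) -> None:
    """Sequence variants as FASTA so external models can also be probed."""
    from pathlib import Path

    lines = [f">{name}\n{seq}" for name, seq in variants.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# variant constructors
# ---------------------------------------------------------------------------


def randomize_positions(
    sequence: str,
    positions,
    freqs: ResidueFrequencies,
    rng: np.random.Generator,
) -> str:
    """Resample the listed 0-based positions independently from ``freqs``.

    All other positions are unchanged; length is preserved. A resampled
    position may draw its original residue.
    """
    positions = sorted(set(int(p) for p in positions))
    if positions and (positions[0] < 0 or positions[-1] >= len(sequence)):
        raise IndexError(
            f"position out of range for sequence of length {len(sequence)}"
        )
    seq = list(sequence)
    for pos, res in zip(positions, freqs.draw(rng, len(positions))):
        seq[pos] = res
    return "".join(seq)


def cumulative_position_sets(length: int, direction: str, segment: int = DEFAULT_SEGMENT):
    """Nested targeted-position sets for cumulative randomization.

    Step k targets the first (N→C) or last (C→N) ``min(k*segment, length)``
    positions; the final step always covers the whole sequence.
    """
    if direction not in ("n_to_c", "c_to_n"):
        raise ValueError("direction must be 'n_to_c' or 'c_to_n'")
    sets = []
    k = 1
    while True:
        span = min(k * segment, length)
        if direction == "n_to_c":
            sets.append(frozenset(range(span)))
        else:
            sets.append(frozenset(range(length - span, length)))
        if span == length:
            return sets
        k += 1


def cumulative_variants(
    sequence: str,
    direction: str,
    freqs: ResidueFrequencies,
    seed: int,
    segment: int = DEFAULT_SEGMENT,
) -> list[str]:
    """Variants with cumulatively growing randomized prefixes/suffixes.

    Variant k extends variant k-1's targeted set: residues drawn at earlier
    steps are kept and only the newly targeted segment is drawn, exactly as
    in iterative segment-wise randomization.
    """
    rng = np.random.default_rng(seed)
    sets = cumulative_position_sets(len(sequence), direction, segment)
    variants = []
    current = sequence
    done: frozenset[int] = frozenset()
    for target in sets:
        new_positions = target - done
        current = randomize_positions(current, new_positions, freqs, rng)
        variants.append(current)
        done = target
    return variants


def control_variants(
    sequence: str,
    counts,
    freqs: ResidueFrequencies,
    seed: int,
) -> list[str]:
    """For each count c, randomize c distinct uniformly chosen positions.

    Position sets are drawn fresh at every step (not cumulative), matching
    per-iteration positional controls.
    """
    rng = np.random.default_rng(seed)
    out = []
    for c in counts:
        c = int(c)
        if c > len(sequence):
            raise ValueError(f"count {c} exceeds sequence length {len(sequence)}")
        positions = rng.choice(len(sequence), size=c, replace=False)
        out.append(randomize_positions(sequence, positions, freqs, rng))
    return out


def _merged_ranges(
    motif_ranges, length: int
) -> list[tuple[int, int]]:
    """Validate 1-based inclusive ranges; merge overlaps with a warning."""
    ranges = sorted(tuple(r) for r in motif_ranges)
    if not ranges:
        raise ValueError("no motif ranges given")
    for start, end in ranges:
        if not (1 <= start <= end <= length):
            raise ValueError(f"motif range {start}-{end} outside sequence of length {length}")
    merged = [list(ranges[0])]
    overlapped = False
    for start, end in ranges[1:]:
        if start <= merged[-1][1]:
            overlapped = True
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    if overlapped:
        warnings.warn("overlapping motif ranges merged", stacklevel=3)
    return [tuple(m) for m in merged]


def motif_positions(motif_ranges, length: int) -> list[int]:
    """0-based positions covered by the (merged) 1-based motif ranges."""
    out: set[int] = set()
    for start, end in _merged_ranges(motif_ranges, length):
        out.update(range(start - 1, end))
    return sorted(out)


def mask_motif(
    sequence: str,
    motif_ranges,
    mode: str,
    freqs: ResidueFrequencies | None = None,
    seed: int = 0,
) -> str:
    """Mask motif windows by randomization or alanine replacement."""
    positions = motif_positions(motif_ranges, len(sequence))
    if mode == "alanine":
        seq = list(sequence)
        for p in positions:
            seq[p] = "A"
        return "".join(seq)
    if mode == "randomize":
        if freqs is None:
            raise ValueError("randomize mode requires residue frequencies")
        return randomize_positions(
            sequence, positions, freqs, np.random.default_rng(seed)
        )
    raise ValueError(f"unknown masking mode {mode!r}")


def mask_random_control(
    sequence: str,
    n_positions: int,
    mode: str,
    freqs: ResidueFrequencies | None = None,
    seed: int = 0,
) -> str:
    """Control: modify ``n_positions`` random positions by the same operator."""
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(sequence), size=n_positions, replace=False)
    if mode == "alanine":
        seq = list(sequence)
        for p in positions:
            seq[p] = "A"
        return "".join(seq)
    if mode == "randomize":
        if freqs is None:
            raise ValueError("randomize mode requires residue frequencies")
        return randomize_positions(sequence, positions, freqs, rng)
    raise ValueError(f"unknown masking mode {mode!r}")


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------


@dataclass
class PerturbationCurve:
    """Reproduction counts along a randomization trajectory.

    One row per (step, repeat); ``n_residues_randomized`` starts at 0 (the
    unperturbed sequence) and ends at the full sequence length.
    """

    sequence_id: str
    kind: str
    table: pd.DataFrame  # columns: step, n_residues_randomized, repeat, n_uq_repro

    def summarize(self) -> pd.DataFrame:
        """Mean and sample standard deviation per step (sd absent for 1 repeat)."""
        from .stats import summarize_curve

        grouped = self.table.pivot_table(
            index="n_residues_randomized", columns="repeat", values="n_uq_repro"
        )
        return summarize_curve(
            [grouped[c].to_numpy() for c in grouped.columns],
            grid=grouped.index.to_numpy(),
        )


def _batched_counts(model, variants, test_compounds, plan):
    """Reproduction count for each variant, sampled in shared batches."""
    from .evaluation import SampleSet

    grouped = model.sample_strings_many(
        variants, plan.n_samples, temperature=plan.temperature, seed=plan.seed
    )
    counts = []
    for raw in grouped:
        ss = SampleSet("variant", raw, plan.temperature, plan.seed)
        counts.append(count_reproduced(ss, test_compounds))
    return counts


def run_experiment(
    model: SequenceToCompoundTransformer,
    test: PairDataset,
    sequence_id: str,
    plan: PerturbationPlan,
    freqs: ResidueFrequencies,
):
    """Execute a perturbation plan for one test sequence.

    Cumulative kinds return a :class:`PerturbationCurve` over
    ``plan.repeats`` independent randomizations (step 0 is the unperturbed
    sequence, evaluated once per repeat with an independent sample draw).
    Masking and full-randomization kinds return a DataFrame of per-trial
    reproduction counts ready for statistical comparison.
    """
    record = test.sequences[sequence_id]
    sequence = record.residues
    test_compounds = test.compounds_of(sequence_id)
    if not test_compounds:
        raise ValueError(f"{sequence_id} has no associated test compounds")
    length = len(sequence)
    base_seed = plan.seed

    if plan.kind in (
        "cumulative_n_to_c",
        "cumulative_c_to_n",
        "cumulative_random_control",
    ):
        sets = cumulative_position_sets(length, "n_to_c", plan.segment)
        step_counts = [0] + [len(s) for s in sets]
        variants, meta = [], []
        for rep in range(plan.repeats):
            if plan.kind == "cumulative_random_control":
                rep_variants = control_variants(
                    sequence, step_counts[1:], freqs, seed=base_seed + 1000 * rep
                )
            else:
                direction = "n_to_c" if plan.kind == "cumulative_n_to_c" else "c_to_n"
                rep_variants = cumulative_variants(
                    sequence,
                    direction,
                    freqs,
                    seed=base_seed + 1000 * rep,
                    segment=plan.segment,
                )
            for step, (n_rand, variant) in enumerate(
                zip(step_counts, [sequence] + rep_variants)
            ):
                variants.append(variant)
                meta.append((step, n_rand, rep))
        counts = _batched_counts(model, variants, test_compounds, plan)
        rows = [
            {
                "step": step,
                "n_residues_randomized": n_rand,
                "repeat": rep,
                "n_uq_repro": count,
            }
            for (step, n_rand, rep), count in zip(meta, counts)
        ]
        return PerturbationCurve(sequence_id, plan.kind, pd.DataFrame(rows))

    if plan.kind == "full_randomization":
        variants = [
            randomize_positions(
                sequence, range(length), freqs, np.random.default_rng(base_seed + rep)
            )
            for rep in range(plan.repeats)
        ]
    else:
        ranges = plan.motif_ranges or record.motif_ranges
        if not ranges:
            raise ValueError(f"{sequence_id} has no motif ranges")
        n_motif = len(motif_positions(ranges, length))
        mode = "alanine" if plan.kind.endswith("alanine") else "randomize"
        is_control = plan.kind.startswith("motif_random_control")
        variants = []
        for rep in range(plan.repeats):
            if is_control:
                variants.append(
                    mask_random_control(
                        sequence, n_motif, mode, freqs, seed=base_seed + 1000 * rep
                    )
                )
            else:
                variants.append(
                    mask_motif(
                        sequence, ranges, mode, freqs, seed=base_seed + 1000 * rep
                    )
                )
    counts = _batched_counts(model, variants, test_compounds, plan)
    return pd.DataFrame(
        [{"repeat": rep, "n_uq_repro": c} for rep, c in enumerate(counts)]
    )
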