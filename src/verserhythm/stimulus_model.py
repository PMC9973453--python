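"""Metrical grids and tack substitution for metered poem stimuli.

A poem stimulus is represented as an ordered grid of syllable slots, each
carrying a stress mark (``s`` strong / ``w`` weak) dictated by the poem's
meter: iambic lines alternate weak-strong starting weak, trochaic lines
start strong.  Odd-length (catalectic) lines truncate the alternation.
Random slots in later lines can be replaced by the lexically meaningless
syllable "tack", which keeps the slot's metrical stress but removes its
lexical identity.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Meter",
    "StressMark",
    "SyllableSlot",
    "LineSpec",
    "PoemSpec",
    "build_grid",
    "place_tacks",
    "study_poems",
    "poems_to_table",
    "poems_from_table",
]

TACK_LABEL = "tack"

#: distinct lexical syllable types in the study corpus; recurring types are
#: what the syllable random intercept groups over
N_SYLLABLE_TYPES = 431

#: Per-poem syllable totals of the six study stimuli (three iambic, three
#: trochaic), with the default line allocation used by the synthetic study.
STUDY_STIMULI = (
    # (poem_id, meter, total syllables, number of lines)
    ("A1", "iambic", 273, 33),
    ("D2", "trochaic", 270, 33),
    ("C2", "trochaic", 76, 9),
    ("D1", "iambic", 68, 8),
    ("E1", "iambic", 154, 19),
    ("F2", "trochaic", 150, 18),
)


class Meter(str, enum.Enum):
    """Binary meter of a poem: iambic (weak-strong feet) or trochaic."""

    IAMBIC = "iambic"
    TROCHAIC = "trochaic"


class StressMark(str, enum.Enum):
    """Predicted metrical stress of a syllable slot."""

    STRONG = "s"
    WEAK = "w"


@dataclass(frozen=True)
class SyllableSlot:
    """One syllable position in a line of the metrical grid."""

    label: str
    word_idx: int
    stress: StressMark
    is_tack: bool = False


@dataclass(frozen=True)
class LineSpec:
    """An ordered sequence of syllable slots forming one verse line."""

    slots: tuple[SyllableSlot, ...]

    def __len__(self) -> int:
        return len(self.slots)


@dataclass(frozen=True)
class PoemSpec:
    """A poem stimulus: metrical grid plus tack annotation.

    Invariants: at least one line, every line has at least two slots, and
    stress alternates according to ``meter`` (catalectic truncation allowed).
    """

    poem_id: str
    meter: Meter
    lines: tuple[LineSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("a poem needs at least one line")
        for i, line in enumerate(self.lines, start=1):
            if len(line) < 2:
                raise ValueError(f"line {i} has fewer than 2 syllable slots")

    @property
    def n_syllables(self) -> int:
        return sum(len(line) for line in self.lines)

    def iter_slots(self):
        """Yield (line_no, syll_idx_in_line, syll_idx_in_poem, slot), 1-based."""
        k = 0
        for line_no, line in enumerate(self.lines, start=1):
            for j, slot in enumerate(line.slots, start=1):
                k += 1
                yield line_no, j, k, slot


def _stress_pattern(meter: Meter, n: int) -> list[StressMark]:
    first, second = (
        (StressMark.WEAK, StressMark.STRONG)
        if meter is Meter.IAMBIC
        else (StressMark.STRONG, StressMark.WEAK)
    )
    return [first if k % 2 == 0 else second for k in range(n)]


def build_grid(
    meter: Meter | str,
    n_lines: int,
    sylls_per_line: int | list[int],
    poem_id: str = "poem",
) -> PoemSpec:
    """Build a strictly alternating metrical grid.

    Parameters
    ----------
    meter : Meter or str
        ``iambic`` lines start weak, ``trochaic`` lines start strong.
    n_lines : int
        Number of verse lines (>= 1).
    sylls_per_line : int or list of int
        Slots per line (each >= 2); a scalar applies to all lines.  Odd
        lengths yield catalectic lines (truncated alternation).
    """
    meter = Meter(meter)
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    if isinstance(sylls_per_line, int):
        lengths = [sylls_per_line] * n_lines
    else:
        lengths = list(sylls_per_line)
        if len(lengths) != n_lines:
            raise ValueError("per-line length list must match n_lines")
    lines = []
    word = 0
    for m in lengths:
        if m < 2:
            raise ValueError(f"every line needs >= 2 slots, got {m}")
        stresses = _stress_pattern(meter, m)
        slots = []
        for j, st in enumerate(stresses):
            # Default lexical layout: disyllabic words spanning each foot.
            if j % 2 == 0:
                word += 1
            slots.append(SyllableSlot(label=f"syl{word}_{j % 2}", word_idx=word, stress=st))
        lines.append(LineSpec(tuple(slots)))
    return PoemSpec(poem_id=poem_id, meter=meter, lines=tuple(lines))


def place_tacks(
    poem: PoemSpec,
    rate: float,
    seed: int | np.random.Generator,
    min_line: int = 3,
    max_per_line: int = 5,
) -> PoemSpec:
    """Replace random slots by the syllable "tack", preserving stress.

    Tacks occur only in lines with 1-based index >= ``min_line`` and are
    drawn as independent per-slot Bernoulli(``rate``) events, capped at
    ``max_per_line`` tacks in any one line.  Only the label and the
    ``is_tack`` flag change; stress, line and word structure are untouched.
    Deterministic under a fixed seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"tack rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    new_lines = []
    for line_no, line in enumerate(poem.lines, start=1):
        if line_no < min_line or rate == 0.0:
            new_lines.append(line)
            continue
        hits = np.flatnonzero(rng.random(len(line)) < rate)
        if len(hits) > max_per_line:
            hits = rng.choice(hits, size=max_per_line, replace=False)
            hits.sort()
        hitset = set(int(h) for h in hits)
        slots = tuple(
            replace(s, label=TACK_LABEL, is_tack=True) if j in hitset else s
            for j, s in enumerate(line.slots)
        )
        new_lines.append(LineSpec(slots))
    return PoemSpec(poem_id=poem.poem_id, meter=poem.meter, lines=tuple(new_lines))


def _line_lengths(total: int, n_lines: int) -> list[int]:
    base, extra = divmod(total, n_lines)
    return [base + 1 if i < extra else base for i in range(n_lines)]


def relabel_with_type_pool(
    poems: list[PoemSpec],
    n_types: int = N_SYLLABLE_TYPES,
    seed: int | np.random.Generator = 0,
) -> list[PoemSpec]:
    """Relabel non-tack slots from a recurring pool of lexical types.

    Real poems reuse lexical syllables, and a recurring syllable occupies
    strong as well as weak grid positions; the syllable random intercept
    groups over those recurring types.  Each regular slot is assigned one
    of ``n_types`` identities uniformly at random (balanced counts,
    deterministic under the seed), so types cross the stress factor as
    they do in natural text.  Tack slots keep their label.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_regular = sum(
        1 for p in poems for line in p.lines for s in line.slots if not s.is_tack
    )
    assignment = rng.permutation(np.arange(n_regular) % n_types)
    counter = 0
    out = []
    for poem in poems:
        new_lines = []
        for line in poem.lines:
            slots = []
            for s in line.slots:
                if s.is_tack:
                    slots.append(s)
                else:
                    slots.append(replace(s, label=f"type{assignment[counter]:03d}"))
                    counter += 1
            new_lines.append(LineSpec(tuple(slots)))
        out.append(PoemSpec(poem_id=poem.poem_id, meter=poem.meter, lines=tuple(new_lines)))
    return out


def study_poems(tack_rate: float = 0.17, seed: int | np.random.Generator = 0) -> list[PoemSpec]:
    """The six default study stimuli with tacks placed.

    Syllable totals (273, 270, 76, 68, 154, 150; 991 slots over 120 lines)
    follow the study design; lines are allocated proportionally with 8-9
    syllables each.  ``tack_rate`` is the per-slot substitution probability
    on eligible lines (index >= 3).  Regular slots are labeled from the
    recurring type pool (see :func:`relabel_with_type_pool`).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    poems = []
    for poem_id, meter, total, n_lines in STUDY_STIMULI:
        grid = build_grid(meter, n_lines, _line_lengths(total, n_lines), poem_id=poem_id)
        poems.append(place_tacks(grid, tack_rate, rng))
    return relabel_with_type_pool(poems, seed=rng)


# ---------------------------------------------------------------------------
# TSV serialization

_TABLE_COLS = ["poem_id", "meter", "line_no", "word_idx", "syll_idx_in_line", "label", "stress", "is_tack"]


def poems_to_table(poems: list[PoemSpec]) -> pd.DataFrame:
    rows = []
    for poem in poems:
        for line_no, j, _k, slot in poem.iter_slots():
            rows.append(
                (poem.poem_id, poem.meter.value, line_no, slot.word_idx, j,
                 slot.label, slot.stress.value, slot.is_tack)
            )
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def poems_from_table(table: pd.DataFrame | str) -> list[PoemSpec]:
    if isinstance(table, (str, io.IOBase)):
        table = pd.read_csv(table, sep="\t")
    poems = []
    for poem_id, grp in table.groupby("poem_id", sort=False):
        meter = Meter(grp["meter"].iloc[0])
        lines = []
        for _ln, lg in grp.groupby("line_no", sort=True):
            lg = lg.sort_values("syll_idx_in_line")
            slots = tuple(
                SyllableSlot(
                    label=str(r.label),
                    word_idx=int(r.word_idx),
                    stress=StressMark(r.stress),
                    is_tack=bool(r.is_tack),
                )
                for r in lg.itertuples()
            )
            lines.append(LineSpec(slots))
        poems.append(PoemSpec(poem_id=str(poem_id), meter=meter, lines=tuple(lines)))
    return poems
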