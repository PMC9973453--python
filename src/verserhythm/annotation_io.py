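"""Praat TextGrid I/O and construction of the chronological syllable table.

Handles both text dialects of the TextGrid format ("long", with
``key = value`` lines, and "short", bare values) in UTF-8 or UTF-16, for
interval tiers.  Point tiers are ignored with a warning.  Times are seconds;
intervals are treated as closed-open ``[xmin, xmax)``.

The syllable table joins a recording's syllable tier to the poem's metrical
grid: each non-empty syllable interval, in chronological order, is matched
to one grid slot and annotated with stress, tack status and the tack's
1-based ordinal within its line.  Empty-label intervals are pauses and are
never matched.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .stimulus_model import PoemSpec

__all__ = [
    "IntervalTier",
    "TextGridParseError",
    "read_textgrid",
    "write_textgrid",
    "build_syllable_table",
    "SYLLABLE_TABLE_COLUMNS",
]

log = logging.getLogger(__name__)


class TextGridParseError(ValueError):
    """Malformed TextGrid input; carries the offending 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass
class IntervalTier:
    """A named, ordered list of non-overlapping labeled time intervals."""

    name: str
    intervals: list[tuple[float, float, str]]

    def validate(self) -> None:
        prev_xmax = None
        for i, (xmin, xmax, _text) in enumerate(self.intervals, start=1):
            if not xmin < xmax:
                raise ValueError(
                    f"tier {self.name!r}, interval {i}: xmin {xmin} must be < xmax {xmax}"
                )
            if prev_xmax is not None and xmin < prev_xmax - 1e-12:
                raise ValueError(
                    f"tier {self.name!r}, interval {i}: overlaps previous interval"
                )
            prev_xmax = xmax

    @property
    def xmin(self) -> float:
        return self.intervals[0][0] if self.intervals else 0.0

    @property
    def xmax(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0


# ---------------------------------------------------------------------------
# Reading


def _decode(raw: bytes) -> str:
    if raw.startswith(b"\xfe\xff") or raw.startswith(b"\xff\xfe"):
        return raw.decode("utf-16")
    return raw.decode("utf-8-sig")


class _Tokens:
    """Sequential reader over the meaningful tokens of either dialect.

    In both dialects every datum is either a number or a double-quoted
    string; the long dialect adds ``key =`` prefixes and decorative lines,
    which we strip.  Quotes inside strings are doubled.
    """

    _NUM = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")

    def __init__(self, text: str):
        self.items: list[tuple[object, int]] = []  # (value, line_no)
        for line_no, line in enumerate(text.splitlines(), start=1):
            s = line.strip()
            if not s:
                continue
            if "=" in s:
                s = s.split("=", 1)[1].strip()
            elif s.endswith(":") or s.startswith(("item", "intervals", "points")):
                # decorative headers like "item []:" / "intervals [1]:"
                if not s.startswith('"'):
                    continue
            self._scan(s, line_no)
        self.pos = 0

    def _scan(self, s: str, line_no: int) -> None:
        i = 0
        while i < len(s):
            c = s[i]
            if c.isspace():
                i += 1
            elif c == '"':
                j = i + 1
                out = []
                while True:
                    if j >= len(s):
                        raise TextGridParseError("unterminated string", line_no)
                    if s[j] == '"':
                        if j + 1 < len(s) and s[j + 1] == '"':
                            out.append('"')
                            j += 2
                        else:
                            j += 1
                            break
                    else:
                        out.append(s[j])
                        j += 1
                self.items.append(("".join(out), line_no))
                i = j
            else:
                m = self._NUM.match(s, i)
                if m:
                    self.items.append((float(m.group()), line_no))
                    i = m.end()
                elif s.startswith("<exists>", i):
                    self.items.append((True, line_no))
                    i += len("<exists>")
                elif s.startswith("<absent>", i):
                    self.items.append((False, line_no))
                    i += len("<absent>")
                else:
                    # stray word (e.g. "tiers?" already consumed via '='); skip token
                    k = i
                    while k < len(s) and not s[k].isspace():
                        k += 1
                    i = k

    def _next(self, kind: type, what: str):
        if self.pos >= len(self.items):
            raise TextGridParseError(f"unexpected end of file, expected {what}")
        value, line_no = self.items[self.pos]
        self.pos += 1
        if kind is float and isinstance(value, bool):
            raise TextGridParseError(f"expected {what}", line_no)
        if not isinstance(value, kind):
            raise TextGridParseError(f"expected {what}, got {value!r}", line_no)
        return value, line_no

    def number(self, what: str = "number") -> tuple[float, int]:
        return self._next(float, what)

    def string(self, what: str = "string") -> tuple[str, int]:
        return self._next(str, what)


def read_textgrid(path: str | Path) -> list[IntervalTier]:
    """Read a Praat TextGrid (long or short dialect, UTF-8 or UTF-16).

    Returns the interval tiers in file order.  Point tiers are skipped with
    a logged warning.  Raises :class:`TextGridParseError` on malformed input
    and ``ValueError`` on invariant violations (e.g. xmax <= xmin).
    """
    text = _decode(Path(path).read_bytes())
    head = text.splitlines()
    if not head or "ooTextFile" not in head[0]:
        raise TextGridParseError('missing \'File type = "ooTextFile"\' header', 1)
    toks = _Tokens(text)
    ftype, _ = toks.string("file type")
    oclass, _ = toks.string("object class")
    if oclass != "TextGrid":
        raise TextGridParseError(f"not a TextGrid object: {oclass!r}", 2)
    toks.number("global xmin")
    toks.number("global xmax")
    # tiers-exist flag: long dialect has <exists>; short has 1/0 on its own line
    if toks.pos < len(toks.items) and isinstance(toks.items[toks.pos][0], bool):
        toks.pos += 1
    n_tiers, _ = toks.number("tier count")
    tiers: list[IntervalTier] = []
    for _t in range(int(n_tiers)):
        tclass, tline = toks.string("tier class")
        name, _ = toks.string("tier name")
        toks.number("tier xmin")
        toks.number("tier xmax")
        n_items, _ = toks.number("interval count")
        if tclass == "TextTier":
            log.warning("ignoring point tier %r", name)
            for _i in range(int(n_items)):
                toks.number("point time")
                toks.string("point mark")
            continue
        if tclass != "IntervalTier":
            raise TextGridParseError(f"unknown tier class {tclass!r}", tline)
        intervals = []
        for i in range(int(n_items)):
            xmin, ln = toks.number("interval xmin")
            xmax, _ = toks.number("interval xmax")
            label, _ = toks.string("interval text")
            if not xmin < xmax:
                raise ValueError(
                    f"tier {name!r}, interval {i + 1} (line {ln}): "
                    f"xmin {xmin} must be < xmax {xmax}"
                )
            intervals.append((xmin, xmax, label))
        tier = IntervalTier(name=name, intervals=intervals)
        tier.validate()
        tiers.append(tier)
    return tiers


# ---------------------------------------------------------------------------
# Writing


def _q(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write_textgrid(
    tiers: list[IntervalTier],
    path: str | Path,
    dialect: str = "long",
    encoding: str = "utf-8",
) -> None:
    """Write interval tiers as a Praat TextGrid parseable by read_textgrid.

    Times are serialized at microsecond precision so that write/read
    round-trips are exact after rounding.
    """
    if dialect not in ("long", "short"):
        raise ValueError(f"dialect must be 'long' or 'short', got {dialect!r}")
    for tier in tiers:
        tier.validate()
    xmin = min((t.xmin for t in tiers), default=0.0)
    xmax = max((t.xmax for t in tiers), default=0.0)
    f = lambda x: f"{x:.6f}"  # noqa: E731  - microsecond precision
    out = ['File type = "ooTextFile"', 'Object class = "TextGrid"', ""]
    if dialect == "long":
        out += [f"xmin = {f(xmin)}", f"xmax = {f(xmax)}", "tiers? <exists>",
                f"size = {len(tiers)}", "item []:"]
        for t_i, tier in enumerate(tiers, start=1):
            out += [f"    item [{t_i}]:",
                    '        class = "IntervalTier"',
                    f"        name = {_q(tier.name)}",
                    f"        xmin = {f(tier.xmin)}",
                    f"        xmax = {f(tier.xmax)}",
                    f"        intervals: size = {len(tier.intervals)}"]
            for i, (a, b, text) in enumerate(tier.intervals, start=1):
                out += [f"        intervals [{i}]:",
                        f"            xmin = {f(a)}",
                        f"            xmax = {f(b)}",
                        f"            text = {_q(text)}"]
    else:
        out += [f(xmin), f(xmax), "<exists>", str(len(tiers))]
        for tier in tiers:
            out += ['"IntervalTier"', _q(tier.name), f(tier.xmin), f(tier.xmax),
                    str(len(tier.intervals))]
            for a, b, text in tier.intervals:
                out += [f(a), f(b), _q(text)]
    data = "\n".join(out) + "\n"
    enc = encoding.lower()
    if enc.startswith("utf-16"):
        Path(path).write_bytes(data.encode("utf-16"))  # BOM included
    else:
        Path(path).write_bytes(data.encode("utf-8"))


# ---------------------------------------------------------------------------
# Syllable table

SYLLABLE_TABLE_COLUMNS = [
    "participant_id", "poem_id", "meter", "line_no", "word_idx",
    "syll_idx_in_line", "syll_idx_in_poem", "label", "stress", "is_tack",
    "tack_index", "onset_s", "offset_s",
]


class AlignmentError(ValueError):
    """Syllable-tier intervals do not match the poem's grid slots."""


def build_syllable_table(
    tiers: list[IntervalTier],
    poem: PoemSpec,
    participant_id: str,
    syllable_tier: str = "syllables",
    strict: bool = True,
) -> pd.DataFrame:
    """Join a syllable tier to the poem grid, one row per syllable token.

    The non-empty intervals of ``syllable_tier``, in order, must correspond
    one-to-one to the poem's slots (strict mode).  In lenient mode a count
    mismatch aligns as many leading intervals as possible and flags the rest
    of the slots as unmatched (rows dropped, warning logged).
    """
    tier = next((t for t in tiers if t.name == syllable_tier), None)
    if tier is None:
        raise AlignmentError(
            f"no tier named {syllable_tier!r}; found {[t.name for t in tiers]}"
        )
    spoken = [(a, b, text) for (a, b, text) in tier.intervals if text.strip() != ""]
    slots = list(poem.iter_slots())
    if len(spoken) != len(slots):
        if strict:
            first_div = min(len(spoken), len(slots)) + 1
            raise AlignmentError(
                f"poem {poem.poem_id!r}: {len(slots)} grid slots but "
                f"{len(spoken)} labeled intervals (first divergence at "
                f"position {first_div})"
            )
        log.warning(
            "poem %r: aligning %d of %d slots (lenient mode)",
            poem.poem_id, min(len(spoken), len(slots)), len(slots),
        )
    rows = []
    tack_counter: dict[int, int] = {}
    for (line_no, j, k, slot), (a, b, _text) in zip(slots, spoken):
        tack_index = None
        if slot.is_tack:
            tack_counter[line_no] = tack_counter.get(line_no, 0) + 1
            tack_index = tack_counter[line_no]
        rows.append((
            participant_id, poem.poem_id, poem.meter.value, line_no,
            slot.word_idx, j, k, slot.label, slot.stress.value, slot.is_tack,
            tack_index, a, b,
        ))
    df = pd.DataFrame(rows, columns=SYLLABLE_TABLE_COLUMNS)
    bad = df["onset_s"] >= df["offset_s"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} tokens with onset >= offset")
    return df
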