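"""Reading, validating and writing wordlist tables and labeled distance matrices.

A wordlist is a varieties x glosses table of orthographic word forms; a
distance matrix is the labeled, symmetric, nonnegative currency that every
downstream stage (ordination, clustering, matrix comparison, panel
selection) consumes. Both live here together with their file formats:
delimited wordlist tables, square labeled-CSV matrices, PHYLIP
lower-triangle matrices, and pair-list files (one ``labelA,labelB,value``
row per population pair, the shape in which published pairwise F_ST values
are typically printed).
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "WordList",
    "DistanceMatrix",
    "ValidationError",
    "read_wordlist",
    "read_matrix",
    "write_matrix",
    "normalize_form",
]

#: Sentinel for an absent word form.
MISSING = None

#: Cell contents treated as missing by default.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "?"})

_WS_RUN = re.compile(r"\s+")

# Newick / PHYLIP-hostile characters that force quoting or rejection.
_PHYLIP_BAD = re.compile(r"[\s,;:()\[\]]")


class ValidationError(ValueError):
    """An input violated a structural invariant (duplicate labels, asymmetry ...)."""


def normalize_form(raw: str) -> str | None:
    """Normalize an orthographic form: Unicode NFC, casefold, trim and
    collapse whitespace. Returns ``MISSING`` if nothing remains.

    Synonym variants separated by "/" are resolved to the first listed
    variant so every (variety, gloss) cell holds exactly one form.
    """
    s = unicodedata.normalize("NFC", raw)
    s = s.split("/", 1)[0]
    s = _WS_RUN.sub(" ", s.strip()).casefold()
    return s if s else MISSING


@dataclass
class WordList:
    """A gloss-aligned multilingual wordlist.

    Parameters
    ----------
    varieties : list of str
        Ordered unique variety (language) identifiers.
    glosses : list of str
        Ordered unique gloss (standardized meaning) identifiers.
    forms : dict
        Mapping ``(variety, gloss) -> form``; absent keys and ``None``
        values both denote a missing entry.
    family : dict, optional
        Mapping variety -> language-family label.
    """

    varieties: list[str]
    glosses: list[str]
    forms: dict[tuple[str, str], str | None]
    family: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.varieties:
            raise ValidationError("no varieties")
        if not self.glosses:
            raise ValidationError("no glosses")
        for name, seq, fold in (
            ("variety", self.varieties, True),
            ("gloss", self.glosses, False),
        ):
            seen: dict[str, str] = {}
            for x in seq:
                if not x:
                    raise ValidationError(f"empty {name} identifier")
                key = x.casefold() if fold else x
                if key in seen:
                    raise ValidationError(f"duplicate {name} identifier: {x!r}")
                seen[key] = x
        vset, gset = set(self.varieties), set(self.glosses)
        for (v, g), f in self.forms.items():
            if v not in vset:
                raise ValidationError(f"form for undeclared variety {v!r}")
            if g not in gset:
                raise ValidationError(f"form for undeclared gloss {g!r}")
            if f == "":
                raise ValidationError(f"empty form at ({v!r}, {g!r}); use MISSING")

    def get(self, variety: str, gloss: str) -> str | None:
        return self.forms.get((variety, gloss), MISSING)

    @property
    def n_missing(self) -> int:
        total = len(self.varieties) * len(self.glosses)
        present = sum(1 for f in self.forms.values() if f is not MISSING)
        return total - present

    @property
    def n_forms(self) -> int:
        return sum(1 for f in self.forms.values() if f is not MISSING)


@dataclass
class DistanceMatrix:
    """A labeled symmetric nonnegative distance matrix.

    ``kind`` tags the currency: ``lexical`` (normalized Levenshtein, in
    [0, 1]), ``genetic`` (pairwise F_ST, in [0, 1]), ``geographic``
    (great-circle kilometers) or ``other``. ``support`` optionally records,
    for lexical matrices, how many shared glosses stand behind each entry.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "other"
    support: np.ndarray | None = None

    KINDS = ("lexical", "genetic", "geographic", "other")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValidationError(f"duplicate labels: {dupes}")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("nonzero diagonal")
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        if self.kind in ("lexical", "genetic") and np.any(self.values > 1):
            raise ValidationError(f"{self.kind} distances must lie in [0, 1]")
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=int)
            if self.support.shape != (n, n):
                raise ValidationError("support shape mismatch")
            off = ~np.eye(n, dtype=bool)
            if np.any(self.support[off] < 1):
                raise ValidationError("support < 1 behind a defined entry")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def condensed(self) -> np.ndarray:
        """Strict lower-triangle values as a 1-D vector (scipy ordering)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(x) for x in labels]
        sub = self.values[np.ix_(idx, idx)]
        sup = self.support[np.ix_(idx, idx)] if self.support is not None else None
        return DistanceMatrix(list(labels), sub, kind=self.kind, support=sup)


# ---------------------------------------------------------------------------
# wordlist reading


def _sniff_delimiter(sample: str) -> str:
    first = sample.splitlines()[0] if sample else ""
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def read_wordlist(
    path: str | Path,
    *,
    delimiter: str | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> WordList:
    """Read a delimited wordlist table.

    Layout: header row = gloss identifiers; column 1 = variety identifier;
    an optional second column named ``family`` carries family labels.
    Cells matching ``missing_tokens`` (after stripping) become MISSING, and
    all forms are orthographically normalized (NFC, casefold, whitespace
    collapse, first "/"-separated variant).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ValidationError("no varieties: empty file")
    header = [h.strip() for h in rows[0]]
    if len(rows) == 1:
        raise ValidationError("no varieties: header-only file")
    has_family = len(header) > 1 and header[1].casefold() == "family"
    first_data_col = 2 if has_family else 1
    glosses = header[first_data_col:]
    if not glosses:
        raise ValidationError("no glosses in header")

    missing = {m.casefold() for m in missing_tokens}
    varieties: list[str] = []
    family: dict[str, str] = {}
    forms: dict[tuple[str, str], str | None] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValidationError(
                f"ragged row {lineno}: {len(row)} fields, expected {len(header)}"
            )
        variety = row[0].strip()
        varieties.append(variety)
        if has_family:
            family[variety] = row[1].strip()
        for gloss, cell in zip(glosses, row[first_data_col:]):
            if cell.strip().casefold() in missing:
                continue
            form = normalize_form(cell)
            if form is not MISSING:
                forms[(variety, gloss)] = form
    return WordList(varieties, glosses, forms, family=family if has_family else None)


def write_wordlist(w: WordList, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a wordlist back to a delimited table (missing cells empty)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        out = csv.writer(fh, delimiter=delimiter)
        header = ["variety"]
        if w.family is not None:
            header.append("family")
        out.writerow(header + list(w.glosses))
        for v in w.varieties:
            row = [v]
            if w.family is not None:
                row.append(w.family.get(v, ""))
            row += [w.get(v, g) or "" for g in w.glosses]
            out.writerow(row)


# ---------------------------------------------------------------------------
# distance-matrix I/O


def write_matrix(
    m: DistanceMatrix, path: str | Path, format: str = "labeled-csv"
) -> None:
    """Write a distance matrix as a square labeled CSV or a PHYLIP
    lower-triangle file (full precision, >= 10 significant digits)."""
    path = Path(path)
    if format == "labeled-csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            out = csv.writer(fh)
            out.writerow([""] + list(m.labels))
            for label, row in zip(m.labels, m.values):
                out.writerow([label] + [_fmt(x) for x in row])
    elif format == "phylip":
        bad = [x for x in m.labels if _PHYLIP_BAD.search(x)]
        if bad:
            raise ValidationError(
                f"labels unrepresentable in phylip (whitespace/metacharacters): {bad}"
            )
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(m.labels)}\n")
            for i, label in enumerate(m.labels):
                cells = " ".join(_fmt(x) for x in m.values[i, :i])
                fh.write(f"{label} {cells}".rstrip() + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def read_matrix(path: str | Path, format: str = "auto", kind: str = "other") -> DistanceMatrix:
    """Read a distance matrix from labeled CSV, PHYLIP, or a pair list.

    ``format='auto'`` distinguishes the three by shape: a PHYLIP file
    starts with a bare integer; a pair list has exactly three columns
    ``labelA,labelB,value`` and no leading empty header cell. A pair list
    must cover all n(n-1)/2 pairs of the label set it implies.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    if format == "auto":
        first = text.splitlines()[0].strip() if text.strip() else ""
        if first.isdigit():
            format = "phylip"
        else:
            cells = next(csv.reader([first]))
            if len(cells) == 3 and cells[0].strip():
                format = "pairs"
            else:
                format = "labeled-csv"
    if format == "labeled-csv":
        return _read_labeled_csv(text, kind)
    if format == "phylip":
        return _read_phylip(text, kind)
    if format == "pairs":
        return _read_pairs(text, kind)
    raise ValueError(f"unknown format {format!r}")


def _read_labeled_csv(text: str, kind: str) -> DistanceMatrix:
    rows = [r for r in csv.reader(io.StringIO(text)) if any(c.strip() for c in r)]
    labels = [c.strip() for c in rows[0][1:]]
    n = len(labels)
    values = np.zeros((n, n))
    for i, row in enumerate(rows[1:]):
        if row[0].strip() != labels[i]:
            raise ValidationError(
                f"row label {row[0]!r} does not match column label {labels[i]!r}"
            )
        values[i] = [float(x) for x in row[1:]]
    return DistanceMatrix(labels, values, kind=kind)


def _read_phylip(text: str, kind: str) -> DistanceMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels: list[str] = []
    values = np.zeros((n, n))
    for i, ln in enumerate(lines[1 : n + 1]):
        parts = ln.split()
        labels.append(parts[0])
        vals = [float(x) for x in parts[1:]]
        if len(vals) != i:
            raise ValidationError(f"phylip row {i + 1} has {len(vals)} values, expected {i}")
        values[i, :i] = vals
        values[:i, i] = vals
    return DistanceMatrix(labels, values, kind=kind)


def _read_pairs(text: str, kind: str) -> DistanceMatrix:
    pairs: dict[frozenset[str], float] = {}
    labels_seen: list[str] = []
    for row in csv.reader(io.StringIO(text)):
        if not any(c.strip() for c in row):
            continue
        if len(row) != 3:
            raise ValidationError(f"pair row needs 3 fields, got {row}")
        a, b, v = row[0].strip(), row[1].strip(), row[2].strip()
        try:
            val = float(v)
        except ValueError:  # header row
            continue
        if a == b:
            raise ValidationError(f"self-pair {a!r}")
        key = frozenset((a, b))
        if key in pairs and pairs[key] != val:
            raise ValidationError(
                f"pair ({a}, {b}) given twice with different values: "
                f"{pairs[key]} vs {val}"
            )
        pairs[key] = val
        for x in (a, b):
            if x not in labels_seen:
                labels_seen.append(x)
    n = len(labels_seen)
    absent = [
        (labels_seen[i], labels_seen[j])
        for i in range(n)
        for j in range(i + 1, n)
        if frozenset((labels_seen[i], labels_seen[j])) not in pairs
    ]
    if absent:
        raise ValidationError(f"pair list incomplete; absent pairs: {absent}")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pairs[frozenset((labels_seen[i], labels_seen[j]))]
    return DistanceMatrix(labels_seen, values, kind=kind)
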