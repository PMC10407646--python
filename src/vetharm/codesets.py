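"""ICD-9-CM / ICD-10 code sets with prefix-matching semantics.

Administrative EHR extracts record diagnosis codes at varying digit depth
("309.81", "30981", "F43.1", "F4310" ...).  All matching here is therefore
done on *normalized* codes (dot-stripped, upper-cased) against lists of
normalized prefixes: a code belongs to a set when some prefix of the same
coding system is a leading substring of the code.  Numeric or letter-numeric
ranges in the configuration file ("800-999", "X71-X83") are expanded to
fixed-width prefixes at load time so that match time never parses V/E/X
codes numerically.

The six required sets (SELF_HARM_EXPLICIT, SUICIDAL_IDEATION,
INJURY_POISONING, MENTAL_DISORDER, TBI, PTSD) drive the self-harm case
definition and exposure phenotyping.  The bundled defaults are a documented
reconstruction of a published ICD-9 self-harm algorithm plus derived ICD-10
ranges; they are configuration, not constants, and can be replaced by any
CSV with columns ``set_name, system, prefix, description``.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "System",
    "ICDCode",
    "CodeSet",
    "CodeSetRegistry",
    "REQUIRED_SET_NAMES",
    "MalformedCodeError",
    "CodeSetConfigError",
    "normalize_code",
    "icd_code",
    "code_matches",
    "expand_prefix_field",
    "load_registry",
    "write_registry",
    "default_codesets_path",
]


class System(str, Enum):
    """Diagnosis coding system."""

    ICD9 = "icd9"
    ICD10 = "icd10"


REQUIRED_SET_NAMES = (
    "SELF_HARM_EXPLICIT",
    "SUICIDAL_IDEATION",
    "INJURY_POISONING",
    "MENTAL_DISORDER",
    "TBI",
    "PTSD",
)


class MalformedCodeError(ValueError):
    """Raised for a diagnosis code that cannot be normalized."""


class CodeSetConfigError(ValueError):
    """Raised when a code-set file violates the registry contract."""


def normalize_code(raw: str, *, context: str | None = None) -> str:
    """Normalize an ICD code: strip whitespace, remove dots, upper-case.

    Idempotent.  Raises :class:`MalformedCodeError` on empty input,
    naming ``context`` (e.g. the offending row) when given.
    """
    if raw is None:
        raise MalformedCodeError(f"missing ICD code ({context or 'no context'})")
    out = str(raw).replace(".", "").strip().upper()
    if not out:
        raise MalformedCodeError(f"empty ICD code ({context or 'no context'})")
    return out


@dataclass(frozen=True)
class ICDCode:
    """A single diagnosis code, kept in raw and normalized form."""

    raw: str
    normalized: str
    system: System

    def __post_init__(self) -> None:
        if "." in self.normalized or self.normalized != self.normalized.upper():
            raise MalformedCodeError(f"code not normalized: {self.normalized!r}")


def icd_code(raw: str, system: System | str) -> ICDCode:
    """Build an :class:`ICDCode` from a raw string and coding system."""
    return ICDCode(raw=raw, normalized=normalize_code(raw), system=System(system))


_RANGE_RE = re.compile(r"^([A-Z]*)(\d+)-([A-Z]*)(\d+)$")


def expand_prefix_field(prefix: str) -> list[str]:
    """Expand a prefix or prefix-range field to a list of literal prefixes.

    ``"800-999"`` -> ``["800", ..., "999"]``; ``"X71-X83"`` ->
    ``["X71", ..., "X83"]``; a plain prefix passes through unchanged.
    Both endpoints of a range must share the letter part and digit width.
    """
    prefix = normalize_code(prefix, context="prefix field")
    m = _RANGE_RE.match(prefix)
    if not m:
        return [prefix]
    lo_alpha, lo_num, hi_alpha, hi_num = m.groups()
    if hi_alpha and hi_alpha != lo_alpha:
        raise CodeSetConfigError(f"range endpoints differ in letter part: {prefix!r}")
    if len(lo_num) != len(hi_num):
        raise CodeSetConfigError(f"range endpoints differ in width: {prefix!r}")
    lo, hi = int(lo_num), int(hi_num)
    if lo > hi:
        raise CodeSetConfigError(f"descending range: {prefix!r}")
    width = len(lo_num)
    return [f"{lo_alpha}{i:0{width}d}" for i in range(lo, hi + 1)]


@dataclass(frozen=True)
class CodeSet:
    """A named collection of (system, prefix) entries with prefix matching."""

    name: str
    entries: tuple[tuple[System, str], ...]
    # prefixes indexed by (system, prefix length) for vectorized matching
    _by_len: Mapping[System, Mapping[int, frozenset[str]]] = field(
        init=False, repr=False, compare=False, hash=False, default=None
    )

    def __post_init__(self) -> None:
        if not self.entries:
            raise CodeSetConfigError(f"code set {self.name!r} has no entries")
        seen: set[tuple[System, str]] = set()
        for system, prefix in self.entries:
            if (system, prefix) in seen:
                raise CodeSetConfigError(
                    f"duplicate entry ({system.value}, {prefix!r}) in set {self.name!r}"
                )
            seen.add((system, prefix))
            if prefix != normalize_code(prefix):
                raise CodeSetConfigError(
                    f"entry {prefix!r} in set {self.name!r} is not normalized"
                )
        by_len: dict[System, dict[int, set[str]]] = {}
        for system, prefix in self.entries:
            by_len.setdefault(system, {}).setdefault(len(prefix), set()).add(prefix)
        frozen = {
            s: {k: frozenset(v) for k, v in d.items()} for s, d in by_len.items()
        }
        object.__setattr__(self, "_by_len", frozen)

    def match_frame(self, codes: pd.Series, systems: pd.Series) -> pd.Series:
        """Vectorized membership test for aligned code/system Series."""
        out = pd.Series(False, index=codes.index)
        for system, by_len in self._by_len.items():
            in_system = systems == system.value
            if not in_system.any():
                continue
            sub = codes[in_system]
            hit = pd.Series(False, index=sub.index)
            for length, prefixes in by_len.items():
                hit |= sub.str[:length].isin(prefixes)
            out.loc[hit.index[hit]] = True
        return out


def code_matches(code_set: CodeSet, code: ICDCode) -> bool:
    """True iff some same-system entry of ``code_set`` prefixes the code."""
    by_len = code_set._by_len.get(code.system)
    if by_len is None:
        logger.warning(
            "no %s entries in set %s; code %s cannot match",
            code.system.value, code_set.name, code.normalized,
        )
        return False
    n = len(code.normalized)
    return any(
        length <= n and code.normalized[:length] in prefixes
        for length, prefixes in by_len.items()
    )


@dataclass(frozen=True)
class CodeSetRegistry:
    """All code sets needed by the phenotyping stage."""

    sets: Mapping[str, CodeSet]
    source: str = "<in-memory>"

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_SET_NAMES if n not in self.sets]
        if missing:
            raise CodeSetConfigError(
                f"code-set source {self.source!r} is missing required sets: "
                + ", ".join(missing)
            )

    def __getitem__(self, name: str) -> CodeSet:
        return self.sets[name]

    def checksum(self) -> str:
        """Deterministic sha256 over sorted entries, for run manifests."""
        h = hashlib.sha256()
        for name in sorted(self.sets):
            for system, prefix in sorted(self.sets[name].entries):
                h.update(f"{name}\t{system.value}\t{prefix}\n".encode())
        return h.hexdigest()


def default_codesets_path() -> Path:
    """Path of the bundled default code-set file."""
    return Path(resources.files("vetharm").joinpath("data/default_codesets.csv"))


def load_registry(path: str | Path | None = None) -> CodeSetRegistry:
    """Load a :class:`CodeSetRegistry` from a CSV code-set file.

    The file has columns ``set_name, system, prefix, description``; the
    prefix column accepts literal prefixes or ranges (``800-999``,
    ``X71-X83``) which are expanded at load time.  ``path=None`` loads the
    bundled defaults.
    """
    path = Path(path) if path is not None else default_codesets_path()
    if not path.exists():
        raise CodeSetConfigError(f"code-set file not found: {path}")
    rows: dict[str, list[tuple[System, str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"set_name", "system", "prefix"}
        if reader.fieldnames is None or not needed.issubset(reader.fieldnames):
            raise CodeSetConfigError(
                f"{path}: expected columns set_name, system, prefix"
            )
        for i, rec in enumerate(reader, start=2):
            name = rec["set_name"].strip()
            try:
                system = System(rec["system"].strip().lower())
            except ValueError as exc:
                raise CodeSetConfigError(
                    f"{path}:{i}: unknown system {rec['system']!r}"
                ) from exc
            for prefix in expand_prefix_field(rec["prefix"]):
                rows.setdefault(name, []).append((system, prefix))
    sets = {name: CodeSet(name=name, entries=tuple(entries))
            for name, entries in rows.items()}
    return CodeSetRegistry(sets=sets, source=str(path))


def write_registry(registry: CodeSetRegistry, path: str | Path) -> None:
    """Write a registry back to CSV (expanded prefixes, no ranges)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["set_name", "system", "prefix", "description"])
        for name in sorted(registry.sets):
            for system, prefix in sorted(registry.sets[name].entries):
                writer.writerow([name, system.value, prefix, ""])
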