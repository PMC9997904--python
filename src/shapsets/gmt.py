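"""GMT (Gene Matrix Transposed) reading and writing, MSigDB dialect.

One set per line: ``name<TAB>description<TAB>elem1<TAB>elem2...``.
The description field is mandatory but may be empty.  Duplicate
elements within a line are collapsed with a warning; lines with no
elements and duplicate set names are rejected with the offending line
number.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

from .family import SetFamily, build_family


class GmtFormatError(ValueError):
    """Malformed GMT content (with the 1-based line number in the message)."""


def read_gmt(path: str | Path) -> tuple[SetFamily, list[str]]:
    """Parse a GMT file into a validated family plus per-set descriptions."""
    path = Path(path)
    named_sets: list[tuple[str, list[str]]] = []
    descriptions: list[str] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path.name}:{lineno}: expected name, description and "
                    f"at least one element (got {len(fields)} fields)"
                )
            name, description, *elements = fields
            elements = [e for e in elements if e]
            if not elements:
                raise GmtFormatError(
                    f"{path.name}:{lineno}: set {name!r} has no elements"
                )
            if name in seen:
                raise GmtFormatError(
                    f"{path.name}:{lineno}: duplicate set name {name!r}"
                )
            seen.add(name)
            if len(set(elements)) != len(elements):
                warnings.warn(
                    f"{path.name}:{lineno}: duplicate elements in set "
                    f"{name!r} collapsed",
                    stacklevel=2,
                )
            named_sets.append((name, elements))
            descriptions.append(description)
    family = build_family(named_sets)
    return family, descriptions


def write_gmt(
    family: SetFamily,
    path: str | Path,
    descriptions: Sequence[str] | None = None,
) -> None:
    """Write a family as GMT; inverse of :func:`read_gmt` on valid files."""
    if descriptions is None:
        descriptions = [""] * family.n_sets
    if len(descriptions) != family.n_sets:
        raise ValueError("one description per set required")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, desc, members in zip(family.names, descriptions, family.members):
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_element_list(path: str | Path) -> list[str]:
    """Read a plain-text element list (one identifier per line)."""
    path = Path(path)
    out: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token:
                out.append(token)
    return out
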