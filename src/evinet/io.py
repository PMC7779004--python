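"""Readers and writers for the on-disk formats.

Five plain-text formats are supported:

* **links** — edge lists in the "protein links detailed" dialect: a header
  line (``protein1 protein2 <channel...> combined_score``) followed by one
  row per unordered pair with integer scores in 0-999. Space- or
  tab-delimited input is auto-detected; output is always tab-delimited and
  sorted by canonical pair.
* **GMT** — one gene set per line: ``name TAB description TAB member...``.
* **ranked** — two-column TSV ``protein TAB value``.
* **complexes** — TSV ``complex_id TAB member,member,...``.
* **covariates** — TSV with header ``protein TAB <covariate>...``.

All files are UTF-8; lines starting with ``#`` are skipped everywhere.
Integer scores map to probabilities as ``s / 1000``; probabilities encode as
``round(1000 * p)`` clipped to ``[0, 999]`` (the dialect has no 1000).
"""

from __future__ import annotations

import math
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import (
    CHANNELS,
    AnnotationFramework,
    AssociationRecord,
    CovariateTable,
    DataError,
    GeneSet,
    GoldStandard,
    Network,
    canonical_pair,
    validate_protein_id,
)


class ParseError(DataError):
    """A malformed input file; the message names the offending line."""


def _data_lines(path: str) -> Iterable[Tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else " "


def score_to_int(p: float) -> int:
    """Encode probability *p* on the 0-999 integer scale (clipped)."""
    return min(999, max(0, int(round(1000.0 * p))))


def int_to_score(s: int) -> float:
    return s / 1000.0


def _parse_int_score(token: str, lineno: int, path: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer score {token!r}") from None
    if not (0 <= value <= 999):
        raise ParseError(f"{path}:{lineno}: score {value} outside [0, 999]")
    return value


def read_links(path: str) -> Network:
    """Read a links file into a :class:`~evinet.core.Network`.

    The header must name ``protein1``, ``protein2``, optionally a subset of
    the known channels, and optionally ``combined_score`` as the last
    column. Duplicate unordered pairs and self-pairs are rejected.
    """
    lines = iter(_data_lines(path))
    try:
        header_lineno, header_line = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty links file") from None
    delim = _detect_delimiter(header_line)
    columns = header_line.split(delim)
    if len(columns) < 2 or columns[0] != "protein1" or columns[1] != "protein2":
        raise ParseError(
            f"{path}:{header_lineno}: header must start with 'protein1', 'protein2'"
        )
    score_columns = columns[2:]
    has_combined = "combined_score" in score_columns
    if has_combined and score_columns[-1] != "combined_score":
        raise ParseError(f"{path}:{header_lineno}: combined_score must be the last column")
    channel_columns = [c for c in score_columns if c != "combined_score"]
    unknown = [c for c in channel_columns if c not in CHANNELS]
    if unknown:
        raise ParseError(f"{path}:{header_lineno}: unknown channel column(s): {unknown}")

    net = Network()
    for lineno, line in lines:
        fields = line.split(delim)
        if len(fields) != len(columns):
            raise ParseError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        try:
            canonical_pair(a, b)
        except DataError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        channel_scores = {
            ch: int_to_score(_parse_int_score(tok, lineno, path))
            for ch, tok in zip(channel_columns, fields[2 : 2 + len(channel_columns)])
        }
        combined = None
        if has_combined:
            combined = int_to_score(_parse_int_score(fields[-1], lineno, path))
        rec = AssociationRecord(a, b, channel_scores=channel_scores, combined=combined)
        try:
            net.add_edge(rec)
        except DataError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return net


def write_links(net: Network, path: str, header_comments: Sequence[str] = ()) -> None:
    """Write a network as a tab-delimited links file, sorted by canonical pair.

    The combined column is written iff every edge carries a combined score;
    a mixture (some edges with, some without) is an error.
    """
    edges = sorted(net.edges(), key=lambda r: r.pair)
    n_combined = sum(1 for r in edges if r.combined is not None)
    if 0 < n_combined < len(edges):
        raise DataError("combined score present on some edges but not all")
    has_combined = n_combined > 0
    present = set()
    for rec in edges:
        present.update(rec.channel_scores)
    channel_columns = [c for c in CHANNELS if c in present]
    columns = ["protein1", "protein2"] + channel_columns
    if has_combined:
        columns.append("combined_score")
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(columns) + "\n")
        for rec in edges:
            fields = [rec.a, rec.b]
            fields += [str(score_to_int(rec.channel_scores.get(c, 0.0))) for c in channel_columns]
            if has_combined:
                fields.append(str(score_to_int(rec.combined)))
            fh.write("\t".join(fields) + "\n")


def read_gmt(path: str, framework_name: Optional[str] = None) -> AnnotationFramework:
    """Read a GMT file (``name TAB description TAB member...``).

    Members are deduplicated; duplicate set names are an error. The
    framework is named after the file stem unless *framework_name* is given.
    """
    sets: List[GeneSet] = []
    seen = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        name, description = fields[0], fields[1]
        members = {m for m in fields[2:] if m}
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen.add(name)
        sets.append(GeneSet(name=name, description=description, members=members))
    if framework_name is None:
        framework_name = os.path.splitext(os.path.basename(path))[0]
    return AnnotationFramework(name=framework_name, sets=sets)


def write_gmt(framework: AnnotationFramework, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene_set in framework:
            members = "\t".join(sorted(gene_set.members))
            fh.write(f"{gene_set.name}\t{gene_set.description}\t{members}\n")


def read_ranked(path: str):
    """Read a two-column protein/value TSV into a RankedProfile."""
    from .core import RankedProfile

    entries: Dict[str, float] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        protein, token = fields
        if protein in entries:
            raise ParseError(f"{path}:{lineno}: duplicate protein {protein!r}")
        try:
            value = float(token)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {token!r}") from None
        if not math.isfinite(value):
            raise ParseError(f"{path}:{lineno}: non-finite value {token!r}")
        entries[protein] = value
    try:
        return RankedProfile(entries)
    except DataError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_ranked(profile, path: str, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for protein in sorted(profile.entries):
            fh.write(f"{protein}\t{profile.entries[protein]!r}\n")


def read_complexes(path: str) -> GoldStandard:
    """Read a complexes TSV (``complex_id TAB member,member,...``)."""
    complexes: Dict[str, List[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        cid, member_field = fields
        if cid in complexes:
            raise ParseError(f"{path}:{lineno}: duplicate complex id {cid!r}")
        members = [m for m in member_field.split(",") if m]
        if len(set(members)) < 2:
            raise ParseError(f"{path}:{lineno}: complex {cid!r} has fewer than 2 members")
        complexes[cid] = members
    return GoldStandard(complexes)


def write_complexes(gold: GoldStandard, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sorted(gold.complexes):
            fh.write(f"{cid}\t{','.join(sorted(gold.complexes[cid]))}\n")


def read_covariates(path: str) -> CovariateTable:
    """Read a covariate TSV with header ``protein TAB <name>...``."""
    lines = iter(_data_lines(path))
    try:
        header_lineno, header_line = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty covariates file") from None
    columns = header_line.split("\t")
    if len(columns) < 2 or columns[0] != "protein":
        raise ParseError(f"{path}:{header_lineno}: header must be 'protein' plus covariate names")
    names = columns[1:]
    if len(names) != len(set(names)):
        raise ParseError(f"{path}:{header_lineno}: duplicate covariate names")
    tables: Dict[str, Dict[str, float]] = {name: {} for name in names}
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise ParseError(f"{path}:{lineno}: expected {len(columns)} fields")
        protein = validate_protein_id(fields[0])
        for name, token in zip(names, fields[1:]):
            if protein in tables[name]:
                raise ParseError(f"{path}:{lineno}: duplicate protein {protein!r}")
            try:
                value = float(token)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value {token!r}") from None
            if not math.isfinite(value):
                raise ParseError(f"{path}:{lineno}: non-finite value {token!r}")
            tables[name][protein] = value
    return CovariateTable(tables)


def write_covariates(cov: CovariateTable, path: str) -> None:
    names = cov.names()
    proteins = sorted({p for name in names for p in cov[name]})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\t" + "\t".join(names) + "\n")
        for protein in proteins:
            row = [protein] + [repr(cov[name][protein]) for name in names]
            fh.write("\t".join(row) + "\n")
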