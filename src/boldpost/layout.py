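"""Data-layout ingestion via path templates, metadata resolution, and
derivative naming.

Path templates describe file trees with tags like ``{subject}`` or
``{subject:[0-9]+}``: a tag matches any non-empty run of characters
within one path segment (never across a ``/``) unless a regular
expression constrains it.  Files from different templates are paired by
their shared tags (subject, session, ...).  Image metadata is resolved
with a fixed precedence: manual override > JSON sidecar > image header.
Output names follow the BIDS-derivatives convention with tag values
sanitized to alphanumeric characters.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath

__all__ = [
    "PathTemplate",
    "FileMatch",
    "MetadataRecord",
    "TemplateParseError",
    "match_files",
    "pair_by_tags",
    "resolve_metadata",
    "derivative_name",
    "sanitize_value",
    "derivative_path",
]

DEFAULT_TAG_REGEX = r"[^/]+"


class TemplateParseError(ValueError):
    """Malformed path-template syntax; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PathTemplate:
    """A path pattern with ``{name}`` / ``{name:regex}`` tags.

    Each tag name may appear at most once; an unconstrained tag matches
    greedily within a single path segment.
    """

    pattern: str
    _tags: tuple[str, ...] = field(init=False, repr=False, compare=False)
    _regex: "re.Pattern[str]" = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        tags, regex = _compile_template(self.pattern)
        object.__setattr__(self, "_tags", tags)
        object.__setattr__(self, "_regex", regex)

    @property
    def tag_names(self) -> tuple[str, ...]:
        return self._tags

    def match(self, path: str) -> "FileMatch | None":
        m = self._regex.fullmatch(path)
        if m is None:
            return None
        return FileMatch(path=path, tags=dict(m.groupdict()), template=self)

    def substitute(self, tags: dict[str, str]) -> str:
        """Substitute tag values back into the pattern, yielding a path."""
        out = self.pattern
        for name in self._tags:
            out = re.sub(r"\{" + re.escape(name) + r"(:[^{}]*)?\}", tags[name].replace("\\", r"\\"), out)
        return out


@dataclass(frozen=True)
class FileMatch:
    """A path matched by a template, with extracted tag values."""

    path: str
    tags: dict[str, str]
    template: PathTemplate | None = None

    def __hash__(self) -> int:
        return hash((self.path, tuple(sorted(self.tags.items()))))


def _compile_template(pattern: str) -> tuple[tuple[str, ...], "re.Pattern[str]"]:
    tags: list[str] = []
    parts: list[str] = []
    i = 0
    n = len(pattern)
    while i < n:
        ch = pattern[i]
        if ch == "{":
            end = pattern.find("}", i)
            if end == -1:
                raise TemplateParseError("unbalanced '{'", i)
            body = pattern[i + 1 : end]
            if not body:
                raise TemplateParseError("empty tag", i)
            if ":" in body:
                name, tag_regex = body.split(":", 1)
            else:
                name, tag_regex = body, DEFAULT_TAG_REGEX
            if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
                raise TemplateParseError(f"invalid tag name {name!r}", i + 1)
            if name in tags:
                raise TemplateParseError(f"duplicate tag name {name!r}", i + 1)
            try:
                re.compile(tag_regex)
            except re.error as exc:
                raise TemplateParseError(f"invalid regex for tag {name!r}: {exc}", i + 1)
            tags.append(name)
            parts.append(f"(?P<{name}>{tag_regex})")
            i = end + 1
        elif ch == "}":
            raise TemplateParseError("unbalanced '}'", i)
        else:
            parts.append(re.escape(ch))
            i += 1
    return tuple(tags), re.compile("".join(parts))


def match_files(template: PathTemplate | str, candidates: list[str]) -> list[FileMatch]:
    """Match candidate paths against a template.

    Returns exactly the candidates consistent with the pattern, in
    lexicographic path order; tag values are extracted greedily within a
    single path segment.  Comparison is case-sensitive.
    """
    if isinstance(template, str):
        template = PathTemplate(template)
    matches = []
    for path in sorted(str(c) for c in candidates):
        m = template.match(path)
        if m is not None:
            matches.append(m)
    return matches


def pair_by_tags(
    matches_a: list[FileMatch], matches_b: list[FileMatch]
) -> tuple[list[tuple[FileMatch, FileMatch]], list[FileMatch]]:
    """Pair two match lists on their shared tag names.

    Entries agree when every tag name present in both lists has equal
    values.  Entries of A without a partner are returned in the second
    element rather than dropped, so the caller can still run the best
    possible pipeline for them.  Two candidate partners with identical
    shared tags are an error.
    """
    if not matches_a:
        return [], []
    shared: set[str] = set()
    if matches_b:
        shared = set(matches_a[0].tags) & set(matches_b[0].tags)
    pairs: list[tuple[FileMatch, FileMatch]] = []
    unpaired: list[FileMatch] = []
    index: dict[tuple, list[FileMatch]] = {}
    for b in matches_b:
        key = tuple((k, b.tags[k]) for k in sorted(shared))
        index.setdefault(key, []).append(b)
    for a in matches_a:
        key = tuple((k, a.tags[k]) for k in sorted(shared))
        partners = index.get(key, [])
        if len(partners) > 1:
            raise ValueError(
                f"ambiguous pairing for {a.path}: candidates "
                f"{[p.path for p in partners]} share tags {dict(key)}"
            )
        if partners:
            pairs.append((a, partners[0]))
        else:
            unpaired.append(a)
    return pairs, unpaired


@dataclass(frozen=True)
class MetadataRecord:
    """Resolved image metadata with the winning source tier per field."""

    repetition_time: float
    echo_time: float | None = None
    slice_timing: tuple[float, ...] | None = None
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.repetition_time > 0:
            raise ValueError(f"repetition_time must be positive, got {self.repetition_time}")


_FIELDS = ("repetition_time", "echo_time", "slice_timing")
_REQUIRED = ("repetition_time",)


def resolve_metadata(
    sidecar: dict | None = None,
    header: dict | None = None,
    override: dict | None = None,
) -> MetadataRecord:
    """Resolve metadata fields with precedence override > sidecar > header.

    The chosen tier for each field is recorded in ``source``.  A sidecar
    value that disagrees with the header raises a warning (headers are a
    fallback and are often stale), never an error.
    """
    tiers = (("override", override or {}), ("sidecar", sidecar or {}), ("header", header or {}))
    resolved: dict = {}
    source: dict[str, str] = {}
    for name in _FIELDS:
        for tier_name, mapping in tiers:
            if name in mapping and mapping[name] is not None:
                resolved[name] = mapping[name]
                source[name] = tier_name
                break
    for name in _REQUIRED:
        if name not in resolved:
            raise ValueError(f"no source supplies required metadata field {name!r}")
    sc, hd = dict(tiers[1][1]), dict(tiers[2][1])
    for name in _FIELDS:
        if name in sc and name in hd and sc[name] != hd[name]:
            warnings.warn(
                f"sidecar and header disagree on {name}: {sc[name]} vs {hd[name]}; "
                "using the sidecar value",
                stacklevel=2,
            )
    st = resolved.get("slice_timing")
    return MetadataRecord(
        repetition_time=float(resolved["repetition_time"]),
        echo_time=float(resolved["echo_time"]) if "echo_time" in resolved else None,
        slice_timing=tuple(float(v) for v in st) if st is not None else None,
        source=source,
    )


_SANITIZE_RE = re.compile(r"[^A-Za-z0-9]+")


def sanitize_value(value: str) -> str:
    """Strip every non-alphanumeric character; case is preserved."""
    cleaned = _SANITIZE_RE.sub("", str(value))
    if not cleaned:
        raise ValueError(f"tag value {value!r} is empty after sanitization")
    return cleaned


def derivative_name(tags: dict[str, str], feature_name: str, suffix: str) -> str:
    """BIDS-derivatives-style file name from tags, a feature, and a suffix.

    Tag values are sanitized to alphanumeric characters and joined as
    ``key-value`` pairs (subject first), e.g.
    ``sub-01A_feature-seedConn_effect.nii.gz``.
    """
    if "subject" not in tags and "sub" not in tags:
        raise ValueError("tags must contain a subject identifier")
    tags = dict(tags)
    for key in ("subject", "sub"):
        # an id like "sub_01-A" already carries the BIDS prefix; strip it
        # (only when a separator follows, so "subject01" stays intact)
        val = tags.get(key)
        if val is not None:
            m = re.match(r"sub[^A-Za-z0-9]+(.+)$", str(val))
            if m:
                tags[key] = m.group(1)
    order = ["subject", "sub", "session", "ses", "task", "run"]
    short = {"subject": "sub", "session": "ses"}
    entities: list[str] = []
    seen: set[str] = set()
    for key in list(order) + sorted(set(tags) - set(order)):
        if key not in tags or key in seen:
            continue
        seen.add(key)
        entity = short.get(key, key)
        entities.append(f"{entity}-{sanitize_value(tags[key])}")
    entities.append(f"feature-{sanitize_value(feature_name)}")
    return "_".join(entities) + f"_{suffix}"


def check_sanitization_collisions(values: list[str]) -> dict[str, list[str]]:
    """Detect distinct raw identifiers that sanitize to the same string.

    Silent collisions would merge subjects in the output tree, so callers
    must treat a non-empty result as a hard error.
    """
    seen: dict[str, list[str]] = {}
    for v in values:
        seen.setdefault(sanitize_value(v), []).append(v)
    return {k: vs for k, vs in seen.items() if len(set(vs)) > 1}


def derivative_path(
    root: str | Path,
    tags: dict[str, str],
    feature_name: str,
    suffix: str,
    toolname: str = "boldpost",
) -> Path:
    """Full output path under ``derivatives/<toolname>/sub-<id>/...``."""
    name = derivative_name(tags, feature_name, suffix)
    sub = sanitize_value(tags.get("subject") or tags.get("sub"))
    return Path(root) / "derivatives" / toolname / f"sub-{sub}" / "func" / name
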