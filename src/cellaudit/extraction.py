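"""Mention and ancestry-statement extraction over text chunks.

The extraction procedure is two-step: a first prompt identifies candidate
human samples in a chunk, a second prompt refines those candidates by
filtering out anything that is not specifically a human cell line or cell
culture (media, reagents, murine lines), and a third prompt pulls any
in-text ancestry descriptors tied to the retained mentions. All three
steps go through a pluggable *completion backend* — a callable taking
(system prompt, user prompt, temperature) and returning response text.

Backends are asked to answer with a JSON array; a tolerant parser also
accepts newline-delimited lists, since model outputs drift. Temperature is
always passed as 0 for determinism. The reference backend here is a fully
deterministic mock driven by a gazetteer (names with species flags) and a
descriptor lexicon — it makes the whole pipeline testable offline. The
live chat-completion adapter is a transport-injected contract, excluded
from any test path.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

from .corpus_io import Chunk

__all__ = [
    "Mention",
    "AncestryStatement",
    "CompletionBackend",
    "BackendError",
    "UnknownPromptError",
    "PromptSet",
    "DEFAULT_PROMPTS",
    "GazetteerEntry",
    "MockBackend",
    "mock_backend",
    "gazetteer_from_lexicon",
    "extract_mentions",
    "refine_mentions",
    "extract_ancestry_statements",
    "parse_array_response",
    "PRIMARY_CULTURE_TERMS",
    "NON_CELL_TERMS",
]

logger = logging.getLogger(__name__)

CULTURE_KINDS = ("cell_line", "primary", "unspecified")

#: common primary-culture surface forms the mock recognizes out of the box
PRIMARY_CULTURE_TERMS = (
    "T cells",
    "B cells",
    "monocytes",
    "macrophages",
    "dermal fibroblasts",
    "keratinocytes",
    "hepatocytes",
    "chondrocytes",
    "PBMCs",
    "HUVECs",
    "whole blood",
    "mesenchymal stem cells",
)

#: culture media / reagents an over-eager first pass may report; the refine
#: step removes them
NON_CELL_TERMS = ("DMEM", "RPMI 1640", "RPMI", "FBS", "Matrigel", "trypsin")


@dataclass(frozen=True)
class Mention:
    """An extracted cell-culture name as written in one chunk."""

    article_id: str
    chunk_index: int
    surface_text: str
    culture_kind: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.surface_text.strip():
            raise ValueError("Mention surface_text must be non-empty")
        if self.culture_kind not in CULTURE_KINDS:
            raise ValueError(f"bad culture_kind {self.culture_kind!r}")


@dataclass(frozen=True)
class AncestryStatement:
    """An in-text ancestry claim tied to a mention in the same chunk."""

    article_id: str
    chunk_index: int
    mention_surface: str
    verbatim_label: str

    def __post_init__(self) -> None:
        if not self.verbatim_label.strip():
            raise ValueError("verbatim_label must be non-empty")


class CompletionBackend(Protocol):
    """Contract for a chat-completion backend."""

    name: str

    def complete(
        self, system_prompt: str, user_prompt: str, temperature: float = 0.0
    ) -> str: ...


class BackendError(RuntimeError):
    """Backend failure (timeout, refusal); carries chunk identity when the
    caller supplies it, and is considered retryable."""


class UnknownPromptError(ValueError):
    """The mock backend received a prompt it has no rule table for."""


@dataclass(frozen=True)
class PromptSet:
    """The three prompt templates; configuration strings, swappable without
    code changes — downstream logic depends only on the parsed array."""

    identify_system: str = (
        "You are an expert biomedical curator. Identify every human-derived "
        "sample — cell lines, primary cell cultures, blood or tissue — "
        "mentioned in the text. Answer with a JSON array of the names "
        "exactly as written."
    )
    identify_user: str = "List the human samples in this text.\nTEXT:\n{text}"
    refine_system: str = (
        "You are an expert biomedical curator. From the candidate list, keep "
        "only names that are specifically human cell lines or human cell "
        "cultures; drop media, reagents, and non-human lines. Answer with a "
        'JSON array of objects {{"name": ..., "kind": "cell_line"|"primary"|'
        '"unspecified"}}.'
    )
    refine_user: str = "CANDIDATES:\n{candidates}\nTEXT:\n{text}"
    ancestry_system: str = (
        "You are an expert biomedical curator. For each listed mention, "
        "report any ancestry descriptor the text itself states for it "
        "(for example a donor described as \"Han Chinese\"). Never infer "
        "ancestry that is not written in the text. Answer with a JSON array "
        'of objects {{"mention": ..., "ancestry": ...}}.'
    )
    ancestry_user: str = "MENTIONS:\n{mentions}\nTEXT:\n{text}"


DEFAULT_PROMPTS = PromptSet()

_FENCE_RE = re.compile(r"^```[a-z]*\n|\n?```$", re.MULTILINE)
_BULLET_RE = re.compile(r"^\s*(?:[-*•]|\d+[.)])\s*")


def parse_array_response(text: str) -> list:
    """Parse a backend response into a list of strings/objects.

    Accepts a JSON array (possibly fenced); falls back to a newline-
    delimited list with optional bullets. Malformed JSON that *looks* like
    JSON yields an empty list with a logged warning — never a crash.
    """
    cleaned = _FENCE_RE.sub("", text).strip()
    if not cleaned:
        return []
    if cleaned[0] in "[{":
        try:
            data = json.loads(cleaned)
        except json.JSONDecodeError:
            logger.warning("unparseable backend response: %.80r", text)
            return []
        if isinstance(data, dict):
            data = [data]
        if not isinstance(data, list):
            logger.warning("backend response is not an array: %.80r", text)
            return []
        return [d for d in data if isinstance(d, (str, dict))]
    return [s for s in (_BULLET_RE.sub("", ln).strip() for ln in cleaned.splitlines()) if s]


def _item_name(item: str | dict) -> str:
    if isinstance(item, dict):
        return str(item.get("name", "")).strip()
    return item.strip()


_PRIMARY_PATTERN = re.compile(
    r"\bprimary\s+(?:human\s+)?([A-Za-z][A-Za-z0-9 ]*?\bcells)\b", re.IGNORECASE
)


def _matches_primary_term(surface: str) -> bool:
    s = surface.casefold()
    return any(s == t.casefold() for t in PRIMARY_CULTURE_TERMS)


def _infer_culture_kind(surface: str, chunk_text: str) -> str:
    """Suffix/keyword heuristic for responses that do not state a kind."""
    if _matches_primary_term(surface):
        return "primary"
    low = chunk_text.casefold()
    if re.search(
        r"\bprimary\b[^.]{0,60}" + re.escape(surface.casefold()), low
    ):
        return "primary"
    if any(ch.isdigit() for ch in surface):
        return "cell_line"
    return "unspecified"


def extract_mentions(chunk: Chunk, backend: CompletionBackend) -> list[Mention]:
    """First extraction pass: candidate human-sample mentions in one chunk."""
    if not chunk.text.strip():
        return []
    prompts = getattr(backend, "prompts", DEFAULT_PROMPTS)
    response = backend.complete(
        prompts.identify_system,
        prompts.identify_user.format(text=chunk.text),
        temperature=0.0,
    )
    mentions: list[Mention] = []
    for item in parse_array_response(response):
        name = _item_name(item)
        if not name:
            continue
        mentions.append(
            Mention(
                article_id=chunk.article_id,
                chunk_index=chunk.chunk_index,
                surface_text=name,
            )
        )
    return mentions


def refine_mentions(
    mentions: Sequence[Mention], chunk: Chunk, backend: CompletionBackend
) -> list[Mention]:
    """Second pass: keep only human cell lines / cell cultures.

    The output is always a subset of the input (matched by surface text);
    culture kind comes from the backend when stated, otherwise from a
    keyword heuristic.
    """
    if not mentions:
        return []
    prompts = getattr(backend, "prompts", DEFAULT_PROMPTS)
    candidates = json.dumps([m.surface_text for m in mentions])
    response = backend.complete(
        prompts.refine_system,
        prompts.refine_user.format(candidates=candidates, text=chunk.text),
        temperature=0.0,
    )
    kept: dict[str, str | None] = {}
    for item in parse_array_response(response):
        name = _item_name(item)
        if name:
            kind = item.get("kind") if isinstance(item, dict) else None
            kept[name.casefold()] = kind if kind in CULTURE_KINDS else None
    out: list[Mention] = []
    for m in mentions:
        key = m.surface_text.casefold()
        if key not in kept:
            continue
        kind = kept[key] or _infer_culture_kind(m.surface_text, chunk.text)
        out.append(replace(m, culture_kind=kind))
    return out


def extract_ancestry_statements(
    chunk: Chunk, mentions: Sequence[Mention], backend: CompletionBackend
) -> list[AncestryStatement]:
    """Third pass: verbatim in-text ancestry descriptors for the retained
    mentions. Statements are only kept when they point at a supplied
    mention — nothing is fabricated for mentions the text says nothing
    about."""
    if not mentions or not chunk.text.strip():
        return []
    prompts = getattr(backend, "prompts", DEFAULT_PROMPTS)
    response = backend.complete(
        prompts.ancestry_system,
        prompts.ancestry_user.format(
            mentions=json.dumps([m.surface_text for m in mentions]), text=chunk.text
        ),
        temperature=0.0,
    )
    known = {m.surface_text.casefold() for m in mentions}
    statements: list[AncestryStatement] = []
    seen: set[tuple[str, str]] = set()
    for item in parse_array_response(response):
        if not isinstance(item, dict):
            continue
        mention = str(item.get("mention", "")).strip()
        label = str(item.get("ancestry", "")).strip()
        if not mention or not label or mention.casefold() not in known:
            continue
        key = (mention.casefold(), label.casefold())
        if key in seen:
            continue
        seen.add(key)
        statements.append(
            AncestryStatement(
                article_id=chunk.article_id,
                chunk_index=chunk.chunk_index,
                mention_surface=mention,
                verbatim_label=label,
            )
        )
    return statements


# ---------------------------------------------------------------------------
# deterministic mock backend


@dataclass(frozen=True)
class GazetteerEntry:
    """One known name for the mock: its species and culture kind."""

    name: str
    species: str = "human"  # human | mouse | hamster | dog | monkey | ...
    kind: str = "unspecified"  # cell_line | primary | unspecified


def gazetteer_from_lexicon(lexicon) -> dict[str, GazetteerEntry]:
    """Build a mock gazetteer covering every lexicon name and synonym."""
    gaz: dict[str, GazetteerEntry] = {}
    for rec in lexicon:
        for name in rec.all_names:
            gaz[name.casefold()] = GazetteerEntry(
                name=name, species="human", kind=rec.culture_kind
            )
    return gaz


_SENTENCE_SPLIT = re.compile(r"[.!?]")


class MockBackend:
    """Deterministic stand-in for a chat-completion model.

    Answers the three prompt templates by case-insensitive dictionary and
    pattern matching over the chunk text: the identify step reports every
    gazetteer hit (regardless of species — over-generation is intentional),
    every primary-culture pattern, and any media term, mimicking a noisy
    first pass; the refine step drops non-human entries and media; the
    ancestry step ties descriptor-lexicon hits to mentions sharing a
    sentence. Identical prompts always yield byte-identical responses; the
    temperature argument is ignored.
    """

    name = "mock"

    def __init__(
        self,
        gazetteer: dict[str, GazetteerEntry],
        descriptor_lexicon: Sequence[str] = (),
        prompts: PromptSet = DEFAULT_PROMPTS,
    ) -> None:
        if not gazetteer:
            raise ValueError("mock backend needs a non-empty gazetteer")
        self.gazetteer = dict(gazetteer)
        self.descriptors = tuple(descriptor_lexicon)
        self.prompts = prompts
        names = sorted(
            {e.name for e in self.gazetteer.values()}
            | set(NON_CELL_TERMS)
            | set(PRIMARY_CULTURE_TERMS),
            key=lambda n: (-len(n), n),
        )
        self._name_re = re.compile(
            "|".join(
                rf"(?<![0-9A-Za-z]){re.escape(n)}(?![0-9A-Za-z])" for n in names
            ),
            re.IGNORECASE,
        )
        self._descriptor_re = (
            re.compile(
                "|".join(
                    rf"(?<![A-Za-z]){re.escape(d)}(?![A-Za-z])"
                    for d in sorted(self.descriptors, key=lambda d: (-len(d), d))
                ),
                re.IGNORECASE,
            )
            if self.descriptors
            else None
        )

    # -- CompletionBackend interface
    def complete(
        self, system_prompt: str, user_prompt: str, temperature: float = 0.0
    ) -> str:
        p = self.prompts
        if system_prompt == p.identify_system:
            return self._identify(_after(user_prompt, "TEXT:\n"))
        if system_prompt == p.refine_system:
            return self._refine(
                _between(user_prompt, "CANDIDATES:\n", "\nTEXT:\n"),
                _after(user_prompt, "TEXT:\n"),
            )
        if system_prompt == p.ancestry_system:
            return self._ancestry(
                _between(user_prompt, "MENTIONS:\n", "\nTEXT:\n"),
                _after(user_prompt, "TEXT:\n"),
            )
        raise UnknownPromptError(f"no rule table for prompt: {system_prompt[:60]!r}")

    # -- task rules
    def _identify(self, text: str) -> str:
        found: list[str] = []
        seen: set[str] = set()
        for m in self._name_re.finditer(text):
            surface = m.group(0)
            if surface.casefold() not in seen:
                seen.add(surface.casefold())
                found.append(surface)
        for m in _PRIMARY_PATTERN.finditer(text):
            surface = m.group(1)
            if surface.casefold() not in seen:
                seen.add(surface.casefold())
                found.append(surface)
        return json.dumps(found)

    def _refine(self, candidates_json: str, text: str) -> str:
        try:
            candidates = json.loads(candidates_json)
        except json.JSONDecodeError:
            candidates = []
        non_cell = {t.casefold() for t in NON_CELL_TERMS}
        kept: list[dict] = []
        for name in candidates:
            key = str(name).casefold()
            if key in non_cell:
                continue
            entry = self.gazetteer.get(key)
            if entry is not None and entry.species != "human":
                continue
            if entry is not None:
                kind = entry.kind
            elif _matches_primary_term(str(name)) or _PRIMARY_PATTERN.search(
                f"primary {name}"
            ):
                kind = "primary"
            else:
                kind = "unspecified"
            kept.append({"name": name, "kind": kind})
        return json.dumps(kept)

    def _ancestry(self, mentions_json: str, text: str) -> str:
        if self._descriptor_re is None:
            return "[]"
        try:
            mentions = [str(m) for m in json.loads(mentions_json)]
        except json.JSONDecodeError:
            mentions = []
        out: list[dict] = []
        seen: set[tuple[str, str]] = set()
        for sentence in _SENTENCE_SPLIT.split(text):
            low = sentence.casefold()
            hits = [m.group(0) for m in self._descriptor_re.finditer(sentence)]
            if not hits:
                continue
            for mention in mentions:
                if mention.casefold() in low:
                    for label in hits:
                        key = (mention.casefold(), label.casefold())
                        if key not in seen:
                            seen.add(key)
                            out.append({"mention": mention, "ancestry": label})
        return json.dumps(out)


def mock_backend(
    gazetteer: dict[str, GazetteerEntry],
    descriptor_lexicon: Sequence[str] = (),
    prompts: PromptSet = DEFAULT_PROMPTS,
) -> MockBackend:
    """Factory mirroring :class:`MockBackend` (kept for API symmetry)."""
    return MockBackend(gazetteer, descriptor_lexicon, prompts)


def _after(text: str, marker: str) -> str:
    idx = text.rfind(marker)
    if idx == -1:
        raise UnknownPromptError(f"user prompt lacks {marker!r} marker")
    return text[idx + len(marker) :]


def _between(text: str, start: str, end: str) -> str:
    s = text.find(start)
    e = text.rfind(end)
    if s == -1 or e == -1 or e < s:
        raise UnknownPromptError(f"user prompt lacks {start!r}/{end!r} markers")
    return text[s + len(start) : e]


# ---------------------------------------------------------------------------
# live adapter contract (transport-injected; never used by the test suite)


class HTTPChatCompletionBackend:
    """Adapter contract for an OpenAI-compatible chat-completion HTTP API.

    The HTTP transport is injected (``post(url, headers, json) -> dict``) so
    this module carries no network dependency; wire in e.g.
    ``requests.post(...).json`` at call time. Disabled by default and never
    exercised offline.
    """

    name = "http-chat"

    def __init__(
        self,
        model: str,
        api_key: str,
        post: Callable[..., dict],
        url: str = "https://api.openai.com/v1/chat/completions",
        prompts: PromptSet = DEFAULT_PROMPTS,
        max_attempts: int = 3,
        backoff: float = 1.0,
    ) -> None:
        self.model = model
        self.api_key = api_key
        self.post = post
        self.url = url
        self.prompts = prompts
        self.max_attempts = max_attempts
        self.backoff = backoff

    def complete(
        self, system_prompt: str, user_prompt: str, temperature: float = 0.0
    ) -> str:
        payload = {
            "model": self.model,
            "temperature": temperature,
            "messages": [
                {"role": "system", "content": system_prompt},
                {"role": "user", "content": user_prompt},
            ],
        }
        headers = {"Authorization": f"Bearer {self.api_key}"}
        last: Exception | None = None
        for attempt in range(self.max_attempts):
            try:
                data = self.post(self.url, headers=headers, json=payload)
                return data["choices"][0]["message"]["content"]
            except Exception as exc:  # noqa: BLE001 - transport opaque
                last = exc
                if attempt + 1 < self.max_attempts:
                    time.sleep(self.backoff * 2**attempt)
        raise BackendError(f"chat completion failed after {self.max_attempts} attempts: {last}")
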