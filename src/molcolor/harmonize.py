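"""Cross-database compound harmonization with EC-number validation.

Two compound collections are matched by compound coloring identifier, tight
(all chemical layers) first and loose (atom + bond type only) second; each
candidate pair is then classified two ways:

* *ID confirmation*: the pair shares a cross-reference (same foreign id in a
  common namespace), or one side cross-references the other side's own id;
* *EC validation*: both compounds participate in metabolic reactions whose
  Enzyme Commission numbers agree on the first three levels (``ec3_verified``)
  or on all four (``ec4_verified``).

A database on disk is a directory of ``<compound_id>.mol`` files plus
optional ``reactions.tsv`` (columns reaction_id, ec, participants) and
``crossrefs.tsv`` (columns compound_id, namespace, foreign_id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .coloring import ColoringConfig
from .identifiers import CompoundIndex, build_index
from .molgraph import MolecularGraph, parse_molfile
from .perception import ReferenceLibrary, normalize_compound

__all__ = [
    "ECNumber",
    "ECParseError",
    "ReactionRecord",
    "CorrespondencePair",
    "HarmonizationReport",
    "match_compounds",
    "confirm_with_ids",
    "validate_with_ec",
    "harmonization_report",
    "read_reactions_tsv",
    "read_crossrefs_tsv",
    "load_database",
    "harmonize_directories",
]

#: reaction_status values, weakest to strongest
STATUSES = ("no_reactions", "in_reactions", "ec3_verified", "ec4_verified")


class ECParseError(ValueError):
    pass


@dataclass(frozen=True)
class ECNumber:
    """Hierarchical 4-level enzyme classification number.

    Wildcard tokens (``-``) may only occupy a suffix, so ``2.3.1.-`` is a
    3-leveled EC; ``specified_depth`` counts the leading non-wildcard tokens.
    """

    levels: tuple[int | None, ...]  # None = wildcard

    def __post_init__(self):
        if not 1 <= len(self.levels) <= 4:
            raise ECParseError(f"EC number must have 1-4 levels, got {self.levels}")
        seen_wild = False
        for tok in self.levels:
            if tok is None:
                seen_wild = True
            elif seen_wild:
                raise ECParseError(
                    f"wildcard only allowed as a suffix: {self.levels}"
                )

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        text = text.strip()
        if text.upper().startswith("EC"):
            text = text[2:].lstrip(" :.")
        parts = text.split(".")
        levels: list[int | None] = []
        for p in parts:
            p = p.strip()
            if p in ("-", "", "?"):
                levels.append(None)
            elif p.isdigit() and int(p) > 0:
                levels.append(int(p))
            else:
                raise ECParseError(f"bad EC token {p!r} in {text!r}")
        while levels and levels[-1] is None and len(levels) > 1:
            # trailing wildcards beyond the first carry no information
            if levels[-2] is None:
                levels.pop()
            else:
                break
        return cls(tuple(levels))

    @property
    def specified_depth(self) -> int:
        d = 0
        for tok in self.levels:
            if tok is None:
                break
            d += 1
        return d

    def agrees(self, other: "ECNumber", depth: int) -> bool:
        """True if both numbers specify at least ``depth`` levels and agree
        on all of them."""
        if self.specified_depth < depth or other.specified_depth < depth:
            return False
        return self.levels[:depth] == other.levels[:depth]

    def __str__(self) -> str:
        return ".".join("-" if t is None else str(t) for t in self.levels)


@dataclass(frozen=True)
class ReactionRecord:
    reaction_id: str
    participants: frozenset[str]
    ecs: tuple[ECNumber, ...] = ()

    def __post_init__(self):
        if not self.participants:
            raise ValueError(f"reaction {self.reaction_id} has no participants")


@dataclass(frozen=True)
class CorrespondencePair:
    left_id: str
    right_id: str
    mode: str  # "tight" | "loose"
    id_confirmed: bool = False
    reaction_status: str = "no_reactions"


# ---------------------------------------------------------------------------
# matching and classification
# ---------------------------------------------------------------------------


def match_compounds(
    index_left: CompoundIndex, index_right: CompoundIndex, mode: str | None = None
) -> list[CorrespondencePair]:
    """One pair per (left, right) compound sharing an identifier key.

    The Cartesian product is taken within each shared key, so one-to-many
    mappings stay visible; no automatic disambiguation is attempted.
    """
    if index_left.mode != index_right.mode:
        raise ValueError(
            f"index mode mismatch: {index_left.mode!r} vs {index_right.mode!r}"
        )
    mode = mode or index_left.mode
    pairs: list[CorrespondencePair] = []
    for key in sorted(set(index_left.mapping) & set(index_right.mapping)):
        for left in index_left.mapping[key]:
            for right in index_right.mapping[key]:
                pairs.append(CorrespondencePair(left, right, mode=mode))
    return pairs


def confirm_with_ids(
    pairs: Sequence[CorrespondencePair],
    crossrefs_left: Iterable[tuple[str, str, str]],
    crossrefs_right: Iterable[tuple[str, str, str]],
    left_namespace: str | None = None,
    right_namespace: str | None = None,
) -> list[CorrespondencePair]:
    """Set ``id_confirmed`` from cross-reference tables.

    A pair is confirmed when both compounds list the same (namespace,
    foreign id), or when one compound's foreign id in the partner database's
    namespace equals the partner's own id (the direct-link case).  When the
    partner namespaces are not named, a foreign id equal to the partner's id
    in any namespace counts.
    """
    refs_l: dict[str, set[tuple[str, str]]] = {}
    for cid, ns, fid in crossrefs_left:
        refs_l.setdefault(cid, set()).add((ns, fid))
    refs_r: dict[str, set[tuple[str, str]]] = {}
    for cid, ns, fid in crossrefs_right:
        refs_r.setdefault(cid, set()).add((ns, fid))

    def direct_link(refs: set[tuple[str, str]], partner_id: str, partner_ns: str | None) -> bool:
        return any(
            fid == partner_id and (partner_ns is None or ns == partner_ns)
            for ns, fid in refs
        )

    out = []
    for p in pairs:
        rl = refs_l.get(p.left_id, set())
        rr = refs_r.get(p.right_id, set())
        confirmed = bool(rl & rr) or direct_link(
            rl, p.right_id, right_namespace
        ) or direct_link(rr, p.left_id, left_namespace)
        out.append(replace(p, id_confirmed=confirmed))
    return out


def validate_with_ec(
    pairs: Sequence[CorrespondencePair],
    reactions_left: Sequence[ReactionRecord],
    reactions_right: Sequence[ReactionRecord],
) -> list[CorrespondencePair]:
    """Set ``reaction_status`` for every pair.

    A pair with either side in no reaction keeps ``no_reactions``; otherwise
    ``in_reactions``, upgraded to ``ec3_verified`` when some left-side EC and
    some right-side EC agree on the first three levels (both specified to
    depth >= 3), and to ``ec4_verified`` when a full 4-level agreement exists.
    """

    def by_compound(reactions: Sequence[ReactionRecord]):
        ecs: dict[str, list[ECNumber]] = {}
        has_rxn: set[str] = set()
        for r in reactions:
            for c in r.participants:
                has_rxn.add(c)
                ecs.setdefault(c, []).extend(r.ecs)
        return has_rxn, ecs

    has_l, ecs_l = by_compound(reactions_left)
    has_r, ecs_r = by_compound(reactions_right)

    out = []
    for p in pairs:
        if p.left_id not in has_l or p.right_id not in has_r:
            status = "no_reactions"
        else:
            status = "in_reactions"
            le = ecs_l.get(p.left_id, [])
            re_ = ecs_r.get(p.right_id, [])
            if any(a.agrees(b, 3) for a in le for b in re_):
                status = "ec3_verified"
                if any(a.agrees(b, 4) for a in le for b in re_):
                    status = "ec4_verified"
        out.append(replace(p, reaction_status=status))
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


@dataclass
class HarmonizationReport:
    """Pair counts per mode x confirmation x reaction status, plus ambiguity.

    ``pairs`` holds the deduplicated pair list: a pair matched under both
    tight and loose appears once, with mode ``tight`` (the stronger claim).
    ``counts`` is a tidy table; ``one_to_many_left`` counts left compounds
    mapped to several right compounds (and vice versa).
    """

    pairs: list[CorrespondencePair]
    counts: pd.DataFrame
    one_to_many_left: int = 0
    one_to_many_right: int = 0

    def count(self, mode: str | None = None, status: str | None = None,
              id_confirmed: bool | None = None) -> int:
        df = self.counts
        if mode is not None:
            df = df[df["mode"] == mode]
        if status is not None:
            df = df[df["reaction_status"] == status]
        if id_confirmed is not None:
            df = df[df["id_confirmed"] == id_confirmed]
        return int(df["count"].sum())


def harmonization_report(
    pairs_tight: Sequence[CorrespondencePair] = (),
    pairs_loose: Sequence[CorrespondencePair] = (),
) -> HarmonizationReport:
    """Summarize one or two harmonization runs over the same databases.

    Loose matching refines to a superset of tight matching on identical
    inputs; pairs present in both are reported once as tight.
    """
    tight_keys = {(p.left_id, p.right_id) for p in pairs_tight}
    deduped = list(pairs_tight) + [
        p for p in pairs_loose if (p.left_id, p.right_id) not in tight_keys
    ]
    rows = []
    for p in deduped:
        rows.append(
            {
                "mode": p.mode,
                "id_confirmed": p.id_confirmed,
                "reaction_status": p.reaction_status,
            }
        )
    if rows:
        counts = (
            pd.DataFrame(rows)
            .groupby(["mode", "id_confirmed", "reaction_status"])
            .size()
            .reset_index(name="count")
        )
    else:
        counts = pd.DataFrame(
            columns=["mode", "id_confirmed", "reaction_status", "count"]
        )
    left_degree: dict[str, int] = {}
    right_degree: dict[str, int] = {}
    for p in deduped:
        left_degree[p.left_id] = left_degree.get(p.left_id, 0) + 1
        right_degree[p.right_id] = right_degree.get(p.right_id, 0) + 1
    return HarmonizationReport(
        pairs=deduped,
        counts=counts,
        one_to_many_left=sum(1 for v in left_degree.values() if v > 1),
        one_to_many_right=sum(1 for v in right_degree.values() if v > 1),
    )


# ---------------------------------------------------------------------------
# directory-layout I/O
# ---------------------------------------------------------------------------


def read_reactions_tsv(path: str | Path) -> list[ReactionRecord]:
    """reactions.tsv: reaction_id TAB comma-separated ECs TAB
    semicolon-separated participant ids.  Unparseable ECs are warned about
    and dropped (the reaction stays, EC-less)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        ecs: list[ECNumber] = []
        for token in str(row["ec"]).split(","):
            token = token.strip()
            if not token:
                continue
            try:
                ecs.append(ECNumber.parse(token))
            except ECParseError as exc:
                warnings.warn(
                    f"reaction {row['reaction_id']}: {exc}; treating as EC-less",
                    stacklevel=2,
                )
        participants = frozenset(
            p.strip() for p in str(row["participants"]).split(";") if p.strip()
        )
        records.append(
            ReactionRecord(str(row["reaction_id"]), participants, tuple(ecs))
        )
    return records


def read_crossrefs_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        (str(r["compound_id"]), str(r["namespace"]), str(r["foreign_id"]))
        for _, r in df.iterrows()
    ]


@dataclass
class Database:
    name: str
    compounds: dict[str, MolecularGraph]
    reactions: list[ReactionRecord] = field(default_factory=list)
    crossrefs: list[tuple[str, str, str]] = field(default_factory=list)


def load_database(path: str | Path, name: str | None = None) -> Database:
    path = Path(path)
    compounds = {}
    for mol in sorted(path.glob("*.mol")):
        compounds[mol.stem] = parse_molfile(mol.read_text(), source_id=mol.stem)
    reactions_path = path / "reactions.tsv"
    crossrefs_path = path / "crossrefs.tsv"
    return Database(
        name=name or path.name,
        compounds=compounds,
        reactions=read_reactions_tsv(reactions_path) if reactions_path.exists() else [],
        crossrefs=read_crossrefs_tsv(crossrefs_path) if crossrefs_path.exists() else [],
    )


def harmonize_databases(
    left: Database,
    right: Database,
    library: ReferenceLibrary | None = None,
    modes: Sequence[str] = ("tight", "loose"),
) -> HarmonizationReport:
    """Full pipeline on in-memory databases: normalize, color, index, match,
    confirm with cross-references, validate with ECs, and summarize."""
    library = library or ReferenceLibrary.default()
    tight_stereo = "tight" in modes

    def normalized(db: Database) -> dict[str, MolecularGraph]:
        out = {}
        for cid, g in db.compounds.items():
            try:
                out[cid] = normalize_compound(g, library, bond_stereo=tight_stereo)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(f"normalization failed for {cid}: {exc}", stacklevel=2)
                out[cid] = g
        return out

    norm_l = normalized(left)
    norm_r = normalized(right)

    def run(cfg: ColoringConfig) -> list[CorrespondencePair]:
        idx_l = build_index(sorted(norm_l.items()), cfg)
        idx_r = build_index(sorted(norm_r.items()), cfg)
        pairs = match_compounds(idx_l, idx_r)
        pairs = confirm_with_ids(
            pairs, left.crossrefs, right.crossrefs,
            left_namespace=left.name, right_namespace=right.name,
        )
        return validate_with_ec(pairs, left.reactions, right.reactions)

    pairs_tight = run(ColoringConfig.tight()) if "tight" in modes else []
    pairs_loose = run(ColoringConfig.loose()) if "loose" in modes else []
    return harmonization_report(pairs_tight, pairs_loose)


def harmonize_directories(
    dir_left: str | Path,
    dir_right: str | Path,
    library: ReferenceLibrary | None = None,
    modes: Sequence[str] = ("tight", "loose"),
) -> HarmonizationReport:
    return harmonize_databases(
        load_database(dir_left), load_database(dir_right), library, modes
    )
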