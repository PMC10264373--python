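"""Metabolic network representation and preprocessing.

A network is a triple (metabolites, reactions, S): S is the stoichiometric
matrix with one row per internal metabolite and one column per reaction.
The extraction machinery downstream assumes every reaction is irreversible
and non-blocked, which is arranged here by splitting each reversible
reaction into a forward/backward pair and deleting blocked reactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "MetabolicNetwork",
    "ReactionOrigin",
    "NetworkFormatError",
    "NetworkValidationError",
    "EmptyNetworkError",
    "load_network",
    "save_network",
    "split_reversible",
    "merge_directions",
    "find_blocked",
    "remove_blocked",
    "preprocess",
]


class NetworkFormatError(ValueError):
    """Raised when a model file cannot be parsed under the named format."""


class NetworkValidationError(ValueError):
    """Raised when a parsed model violates structural invariants."""


class EmptyNetworkError(ValueError):
    """Raised when preprocessing removes every reaction."""


@dataclass(frozen=True)
class ReactionOrigin:
    """Provenance of a column after reversible splitting.

    ``direction`` is ``"native"`` for originally irreversible reactions and
    ``"forward"``/``"backward"`` for the two columns of a split reversible
    reaction; ``original_id`` always names the pre-split reaction.
    """

    original_id: str
    direction: str = "native"  # native | forward | backward


@dataclass
class MetabolicNetwork:
    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    reversibility: np.ndarray  # bool per reaction; all False after splitting
    origin: list[ReactionOrigin] = field(default_factory=list)
    biomass_reaction: Optional[str] = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.reversibility = np.asarray(self.reversibility, dtype=bool)
        if self.S.ndim != 2:
            raise NetworkValidationError("S must be a 2-D matrix")
        if self.S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise NetworkValidationError(
                f"S shape {self.S.shape} does not match "
                f"{len(self.metabolite_ids)} metabolites x "
                f"{len(self.reaction_ids)} reactions"
            )
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise NetworkValidationError("duplicate metabolite identifiers")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise NetworkValidationError("duplicate reaction identifiers")
        if self.reversibility.shape != (len(self.reaction_ids),):
            raise NetworkValidationError("reversibility length mismatch")
        if not self.origin:
            self.origin = [ReactionOrigin(r) for r in self.reaction_ids]
        if len(self.origin) != len(self.reaction_ids):
            raise NetworkValidationError("origin length mismatch")
        if self.biomass_reaction is not None and (
            self.biomass_reaction not in self.reaction_ids
        ):
            raise NetworkValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in network"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    @property
    def all_irreversible(self) -> bool:
        return not bool(self.reversibility.any())


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

_FORMATS = ("sbml", "bigg_json", "tsv")


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf in (".xml", ".sbml"):
        return "sbml"
    if suf == ".json":
        return "bigg_json"
    if suf in (".tsv", ".txt"):
        return "tsv"
    raise NetworkFormatError(f"cannot infer model format from {path.name!r}")


def load_network(
    path: str | Path,
    format: Optional[str] = None,
    biomass_reaction: Optional[str] = None,
) -> MetabolicNetwork:
    """Load a metabolic model into a :class:`MetabolicNetwork`.

    Supported formats: SBML Level 3 (FBC bounds), BIGG-style JSON, and the
    plain-TSV fixture dialect written by :func:`save_network`.  Only internal
    (non-boundary) metabolites become rows of S; exchange reactions are kept
    as columns.  A reaction is flagged reversible iff its lower flux bound is
    negative.  The biomass reaction is detected by a case-insensitive
    "biomass" substring unless ``biomass_reaction`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise NetworkFormatError(f"unknown format {fmt!r}")
    if fmt == "tsv":
        net = _read_tsv(path)
    else:
        net = _read_cobra(path, fmt)
    if biomass_reaction is not None:
        if biomass_reaction not in net.reaction_ids:
            raise NetworkValidationError(
                f"biomass override {biomass_reaction!r} not in model"
            )
        net.biomass_reaction = biomass_reaction
    return net


def _detect_biomass(reaction_ids: Sequence[str]) -> Optional[str]:
    for rid in reaction_ids:
        if "biomass" in rid.lower():
            return rid
    return None


def _read_cobra(path: Path, fmt: str) -> MetabolicNetwork:
    import cobra.io

    try:
        if fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except Exception as exc:  # cobra raises a zoo of exception types
        raise NetworkFormatError(f"failed to parse {path.name}: {exc}") from exc

    reaction_ids = [r.id for r in model.reactions]
    # internal metabolites only: boundary species never constrain the flux
    # cone, and metabolites touching no reaction contribute empty rows
    boundary = {
        m.id for m in model.metabolites if getattr(m, "_boundary", False)
    }
    used = {m.id for r in model.reactions for m in r.metabolites}
    metabolite_ids = [
        m.id for m in model.metabolites if m.id in used and m.id not in boundary
    ]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            i = met_index.get(met.id)
            if i is not None:
                S[i, j] = float(coef)
    reversibility = np.array(
        [r.lower_bound < 0 for r in model.reactions], dtype=bool
    )
    return MetabolicNetwork(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        reversibility=reversibility,
        biomass_reaction=_detect_biomass(reaction_ids),
    )


# TSV dialect: comment header declaring reaction order, reversible ids and
# optional biomass id, then a column-header line, then one row per nonzero
# stoichiometric coefficient.
def _read_tsv(path: Path) -> MetabolicNetwork:
    reactions: list[str] = []
    reversible: set[str] = set()
    biomass: Optional[str] = None
    entries: list[tuple[str, str, float]] = []
    saw_header = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("reactions:"):
                reactions = body.split(":", 1)[1].split()
            elif body.startswith("reversible:"):
                reversible = set(body.split(":", 1)[1].split())
            elif body.startswith("biomass:"):
                biomass = body.split(":", 1)[1].strip() or None
            continue
        fields = line.split("\t")
        if not saw_header:
            if [f.lower() for f in fields[:3]] != [
                "metabolite",
                "reaction",
                "coefficient",
            ]:
                raise NetworkFormatError(
                    f"{path.name}:{lineno}: expected TSV column header"
                )
            saw_header = True
            continue
        if len(fields) != 3:
            raise NetworkFormatError(
                f"{path.name}:{lineno}: expected 3 tab-separated fields"
            )
        met, rxn, coef = fields
        try:
            entries.append((met, rxn, float(coef)))
        except ValueError:
            raise NetworkFormatError(
                f"{path.name}:{lineno}: bad coefficient {coef!r}"
            ) from None
    if not saw_header:
        raise NetworkFormatError(f"{path.name}: missing TSV column header")
    if not reactions:
        seen: list[str] = []
        for _, rxn, _ in entries:
            if rxn not in seen:
                seen.append(rxn)
        reactions = seen
    if len(set(reactions)) != len(reactions):
        raise NetworkValidationError("duplicate reaction identifiers in TSV")
    metabolites: list[str] = []
    for met, _, _ in entries:
        if met not in metabolites:
            metabolites.append(met)
    S = np.zeros((len(metabolites), len(reactions)))
    ridx = {r: j for j, r in enumerate(reactions)}
    midx = {m: i for i, m in enumerate(metabolites)}
    for met, rxn, coef in entries:
        if rxn not in ridx:
            raise NetworkValidationError(
                f"entry references undeclared reaction {rxn!r}"
            )
        S[midx[met], ridx[rxn]] += coef
    reversibility = np.array([r in reversible for r in reactions], dtype=bool)
    return MetabolicNetwork(
        metabolite_ids=metabolites,
        reaction_ids=reactions,
        S=S,
        reversibility=reversibility,
        biomass_reaction=biomass or _detect_biomass(reactions),
    )


def save_network(
    net: MetabolicNetwork, path: str | Path, format: Optional[str] = None
) -> None:
    """Write a network to TSV (fixture dialect) or SBML."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        _write_tsv(net, path)
    elif fmt == "sbml":
        _write_sbml(net, path)
    else:
        raise NetworkFormatError(f"cannot write format {fmt!r}")


def _write_tsv(net: MetabolicNetwork, path: Path) -> None:
    lines = ["# piefm network"]
    lines.append("# reactions: " + " ".join(net.reaction_ids))
    rev = [r for r, f in zip(net.reaction_ids, net.reversibility) if f]
    if rev:
        lines.append("# reversible: " + " ".join(rev))
    if net.biomass_reaction:
        lines.append(f"# biomass: {net.biomass_reaction}")
    lines.append("metabolite\treaction\tcoefficient")
    for i, met in enumerate(net.metabolite_ids):
        for j, rxn in enumerate(net.reaction_ids):
            c = net.S[i, j]
            if c != 0.0:
                lines.append(f"{met}\t{rxn}\t{c:.12g}")
    path.write_text("\n".join(lines) + "\n")


def _write_sbml(net: MetabolicNetwork, path: Path) -> None:
    import cobra
    import cobra.io

    model = cobra.Model("piefm_export")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in net.metabolite_ids}
    rxns = []
    for j, rid in enumerate(net.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = -1000.0 if net.reversibility[j] else 0.0
        rxn.upper_bound = 1000.0
        rxns.append(rxn)
    model.add_reactions(rxns)
    for j, rxn in enumerate(model.reactions):
        coeffs = {
            mets[m]: net.S[i, j]
            for i, m in enumerate(net.metabolite_ids)
            if net.S[i, j] != 0.0
        }
        rxn.add_metabolites(coeffs)
    cobra.io.write_sbml_model(model, str(path))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def split_reversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Decouple every reversible reaction into forward/backward columns.

    The backward column is the negated forward column and is placed
    immediately after it, so the column order is deterministic.  Originally
    irreversible reactions pass through with ``direction="native"``.
    """
    cols: list[np.ndarray] = []
    rids: list[str] = []
    origin: list[ReactionOrigin] = []
    for j, rid in enumerate(net.reaction_ids):
        col = net.S[:, j]
        if net.reversibility[j]:
            rids.append(f"{rid}_fwd")
            cols.append(col)
            origin.append(ReactionOrigin(rid, "forward"))
            rids.append(f"{rid}_bwd")
            cols.append(-col)
            origin.append(ReactionOrigin(rid, "backward"))
        else:
            rids.append(rid)
            cols.append(col)
            origin.append(net.origin[j])
    S = np.column_stack(cols) if cols else np.zeros((net.n_metabolites, 0))
    biomass = net.biomass_reaction
    if biomass is not None and biomass not in rids:
        biomass = f"{biomass}_fwd"  # biomass itself was reversible
    return MetabolicNetwork(
        metabolite_ids=list(net.metabolite_ids),
        reaction_ids=rids,
        S=S,
        reversibility=np.zeros(len(rids), dtype=bool),
        origin=origin,
        biomass_reaction=biomass,
    )


def merge_directions(net: MetabolicNetwork) -> MetabolicNetwork:
    """Invert :func:`split_reversible`, recovering the original columns."""
    cols: list[np.ndarray] = []
    rids: list[str] = []
    rev: list[bool] = []
    skip = False
    for j, org in enumerate(net.origin):
        if skip:
            skip = False
            continue
        if org.direction == "forward":
            cols.append(net.S[:, j])
            rids.append(org.original_id)
            rev.append(True)
            skip = True  # consume the adjacent backward column
        else:
            cols.append(net.S[:, j])
            rids.append(org.original_id)
            rev.append(False)
    return MetabolicNetwork(
        metabolite_ids=list(net.metabolite_ids),
        reaction_ids=rids,
        S=np.column_stack(cols),
        reversibility=np.array(rev, dtype=bool),
        biomass_reaction=net.biomass_reaction
        if net.biomass_reaction in rids
        else (
            net.biomass_reaction[:-4]
            if net.biomass_reaction and net.biomass_reaction.endswith("_fwd")
            else net.biomass_reaction
        ),
    )


def find_blocked(net: MetabolicNetwork, tol: float = 1e-9) -> set[str]:
    """Reactions that carry zero flux in every steady-state mode.

    Detection is FVA-style: maximise each v[r] subject to S v = 0 and unit
    box bounds 0 <= v <= 1 (the box only bounds the cone, any positive bound
    works); r is blocked iff the optimum is <= tol.
    """
    if not net.all_irreversible:
        raise NetworkValidationError("find_blocked expects an all-irreversible network")
    n = net.n_reactions
    blocked: set[str] = set()
    bounds = [(0.0, 1.0)] * n
    for j, rid in enumerate(net.reaction_ids):
        c = np.zeros(n)
        c[j] = -1.0  # linprog minimises
        res = linprog(
            c, A_eq=net.S, b_eq=np.zeros(net.n_metabolites), bounds=bounds,
            method="highs",
        )
        if not res.success:
            raise ArithmeticError(
                f"LP solver failed while probing reaction {rid!r}: {res.message}"
            )
        if -res.fun <= tol:
            blocked.add(rid)
    return blocked


def remove_blocked(net: MetabolicNetwork, tol: float = 1e-9) -> MetabolicNetwork:
    """Delete blocked reactions (and metabolites left with no reaction)."""
    blocked = find_blocked(net, tol=tol)
    keep = [j for j, r in enumerate(net.reaction_ids) if r not in blocked]
    if not keep:
        raise EmptyNetworkError("all reactions are blocked")
    S = net.S[:, keep]
    used_rows = [i for i in range(net.n_metabolites) if np.any(S[i] != 0.0)]
    biomass = net.biomass_reaction
    if biomass in blocked:
        biomass = None
    return MetabolicNetwork(
        metabolite_ids=[net.metabolite_ids[i] for i in used_rows],
        reaction_ids=[net.reaction_ids[j] for j in keep],
        S=S[used_rows, :] if used_rows else S[:0, :],
        reversibility=net.reversibility[keep],
        origin=[net.origin[j] for j in keep],
        biomass_reaction=biomass,
    )


def preprocess(net: MetabolicNetwork, tol: float = 1e-9) -> MetabolicNetwork:
    """split_reversible followed by remove_blocked."""
    return remove_blocked(split_reversible(net), tol=tol)
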