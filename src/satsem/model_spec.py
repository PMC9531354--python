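"""Path-model definitions for satisfaction-index structural equation models.

A satisfaction index model in the ACSI tradition is a directed acyclic graph
of latent variables (public expectations, perceived quality, perceived value,
public satisfaction, public complaints, public trust), each reflected by a
block of ordinal survey items.  Perceived quality may be a second-order
construct whose "indicators" are first-order quality facets.

This module holds the plain data types describing such a model, the shipped
default structure for the URRBMI satisfaction instrument (the 29-item draft
and the final 28-item revision), validation of the type invariants, and a
YAML serialization round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "LatentVariable",
    "StructuralPath",
    "ModelDefinition",
    "default_initial_model",
    "final_model",
    "validate_model",
    "model_to_yaml",
    "model_from_yaml",
]


@dataclass(frozen=True)
class LatentVariable:
    """A latent construct and the survey items that reflect it.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"PS"`` or ``"PQ_policy"``.
    role : {"exogenous", "endogenous"}
        Whether any structural path points into the construct.
    indicators : tuple of str
        Item identifiers reflecting the construct.  Empty for a
        second-order construct (its items are the union of its
        components' items).
    order : {"first", "second"}
        Second-order constructs have first-order constructs, not items,
        as components.
    """

    name: str
    role: str
    indicators: tuple = ()
    order: str = "first"

    def __post_init__(self):
        object.__setattr__(self, "indicators", tuple(self.indicators))


@dataclass(frozen=True)
class StructuralPath:
    """Directed structural relation with its hypothesized sign."""

    source: str
    target: str
    hypothesized_sign: int = +1


@dataclass
class ModelDefinition:
    """A full path-model specification.

    Attributes
    ----------
    latents : list of LatentVariable
    paths : list of StructuralPath
    hoc_components : dict
        Maps each second-order latent name to the ordered list of its
        first-order component names.
    scale : tuple (min_category, max_category)
        Bounds of the ordinal response scale; default ten ordered
        categories 1..10.
    """

    latents: list = field(default_factory=list)
    paths: list = field(default_factory=list)
    hoc_components: dict = field(default_factory=dict)
    scale: tuple = (1, 10)

    # ---- lookups ---------------------------------------------------------

    def latent(self, name: str) -> LatentVariable:
        for lv in self.latents:
            if lv.name == name:
                return lv
        raise KeyError(f"unknown latent variable: {name!r}")

    @property
    def latent_names(self) -> list:
        return [lv.name for lv in self.latents]

    def indicators_of(self, name: str) -> tuple:
        """All items reflecting `name`; for a second-order construct the
        union of its components' items, in component order."""
        lv = self.latent(name)
        if lv.order == "second":
            items = []
            for comp in self.hoc_components.get(name, ()):
                items.extend(self.latent(comp).indicators)
            return tuple(items)
        return lv.indicators

    @property
    def all_indicators(self) -> list:
        """Every item id, in declaration order, without double counting
        second-order constructs."""
        seen, out = set(), []
        for lv in self.latents:
            if lv.order == "second":
                continue
            for it in lv.indicators:
                if it not in seen:
                    seen.add(it)
                    out.append(it)
        return out

    def first_order_of_item(self, item: str) -> str:
        """Name of the first-order latent an item reflects."""
        for lv in self.latents:
            if lv.order == "first" and item in lv.indicators:
                return lv.name
        raise KeyError(f"item {item!r} is not assigned to a first-order latent")

    def predecessors(self, name: str) -> list:
        return [p.source for p in self.paths if p.target == name]

    def successors(self, name: str) -> list:
        return [p.target for p in self.paths if p.source == name]

    def topological_order(self) -> list:
        """Kahn topological sort of the structural graph; raises
        ValueError on a cycle."""
        names = self.latent_names
        indeg = {n: 0 for n in names}
        for p in self.paths:
            indeg[p.target] = indeg.get(p.target, 0) + 1
        queue = [n for n in names if indeg.get(n, 0) == 0]
        order = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for s in self.successors(n):
                indeg[s] -= 1
                if indeg[s] == 0:
                    queue.append(s)
        if len(order) != len(names):
            raise ValueError("structural path set contains a cycle")
        return order

    def drop_items(self, items) -> "ModelDefinition":
        """Return a copy with the given items removed from all blocks."""
        items = set(items)
        new_latents = [
            replace(lv, indicators=tuple(i for i in lv.indicators if i not in items))
            for lv in self.latents
        ]
        return ModelDefinition(
            latents=new_latents,
            paths=list(self.paths),
            hoc_components={k: list(v) for k, v in self.hoc_components.items()},
            scale=self.scale,
        )

    def prune_empty(self) -> "ModelDefinition":
        """Remove first-order latents left without indicators (e.g. a
        facet whose only item was deleted), along with their paths and
        higher-order memberships."""
        empty = {lv.name for lv in self.latents
                 if lv.order == "first" and not lv.indicators}
        if not empty:
            return self
        return ModelDefinition(
            latents=[lv for lv in self.latents if lv.name not in empty],
            paths=[p for p in self.paths
                   if p.source not in empty and p.target not in empty],
            hoc_components={k: [c for c in v if c not in empty]
                            for k, v in self.hoc_components.items()},
            scale=self.scale,
        )


# ---------------------------------------------------------------------------
# Shipped default structure
# ---------------------------------------------------------------------------

_FACETS = {
    "PQ_overall": ("PQ1",),
    "PQ_information": ("PQ2", "PQ3"),
    "PQ_service": ("PQ4", "PQ5"),
    "PQ_policy": ("PQ6", "PQ7", "PQ8", "PQ9", "PQ10", "PQ11", "PQ12"),
    "PQ_institution": ("PQ13", "PQ14", "PQ15", "PQ16", "PQ17"),
}


def default_initial_model() -> ModelDefinition:
    """The 29-item draft instrument.

    Six top-level constructs — public expectations (PE), perceived quality
    (PQ, second order over five facets), perceived value (PV), public
    satisfaction (PS), public complaints (PC), public trust (PT) — plus the
    five PQ facets, with the hypothesized ACSI-style path structure:
    PE→PQ, PE→PV, PE→PS, PQ→PV, PQ→PS, PV→PS positive, PS→PT positive,
    PS→PC negative.
    """
    latents = [
        LatentVariable("PE", "exogenous", ("PE1", "PE2", "PE3")),
        LatentVariable("PQ", "endogenous", (), order="second"),
    ]
    for facet, items in _FACETS.items():
        latents.append(LatentVariable(facet, "endogenous", items))
    latents += [
        LatentVariable("PV", "endogenous", ("PV1", "PV2")),
        LatentVariable("PS", "endogenous", ("PS1", "PS2", "PS3")),
        LatentVariable("PC", "endogenous", ("PC1", "PC2")),
        LatentVariable("PT", "endogenous", ("PT1", "PT2")),
    ]
    paths = [
        StructuralPath("PE", "PQ", +1),
        StructuralPath("PE", "PV", +1),
        StructuralPath("PE", "PS", +1),
        StructuralPath("PQ", "PV", +1),
        StructuralPath("PQ", "PS", +1),
        StructuralPath("PV", "PS", +1),
        StructuralPath("PS", "PT", +1),
        StructuralPath("PS", "PC", -1),
    ]
    return ModelDefinition(
        latents=latents,
        paths=paths,
        hoc_components={"PQ": list(_FACETS)},
        scale=(1, 10),
    )


def final_model() -> ModelDefinition:
    """The final 28-item instrument: the draft with the formal-complaint
    item PC2 removed (11 latent variables, 28 measurement variables)."""
    return default_initial_model().drop_items(["PC2"])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(m: ModelDefinition) -> list:
    """Check all type invariants; return one message per violation
    (an empty list means the model is valid)."""
    violations = []
    names = m.latent_names
    if len(set(names)) != len(names):
        violations.append("duplicate latent variable names")

    seen = {}
    for lv in m.latents:
        for it in lv.indicators:
            if it in seen:
                violations.append(
                    f"duplicate indicator {it!r} (in {seen[it]} and {lv.name})"
                )
            seen[it] = lv.name

    for lv in m.latents:
        if lv.order == "first" and len(lv.indicators) < 1:
            violations.append(f"first-order latent {lv.name} has no indicators")
        if lv.order == "second":
            comps = m.hoc_components.get(lv.name, [])
            if len(comps) < 2:
                violations.append(
                    f"second-order latent {lv.name} has fewer than 2 components"
                )
            if lv.indicators:
                violations.append(
                    f"second-order latent {lv.name} must not own items directly"
                )
            for c in comps:
                if c not in names:
                    violations.append(
                        f"component {c!r} of {lv.name} is not a declared latent"
                    )

    for p in m.paths:
        for end in (p.source, p.target):
            if end not in names:
                violations.append(f"path endpoint {end!r} is not a declared latent")
        if p.hypothesized_sign not in (+1, -1):
            violations.append(
                f"path {p.source}->{p.target} has sign {p.hypothesized_sign}"
            )

    try:
        m.topological_order()
    except ValueError:
        violations.append("cycle in structural paths")

    lo, hi = m.scale
    if not (isinstance(lo, int) and isinstance(hi, int) and lo < hi):
        violations.append(f"invalid response scale {m.scale}")
    return violations


# ---------------------------------------------------------------------------
# Serialization (YAML config format)
# ---------------------------------------------------------------------------

def model_to_dict(m: ModelDefinition) -> dict:
    return {
        "scale": list(m.scale),
        "latents": [
            {
                "name": lv.name,
                "role": lv.role,
                "order": lv.order,
                "indicators": list(lv.indicators),
            }
            for lv in m.latents
        ],
        "paths": [
            {"source": p.source, "target": p.target, "sign": p.hypothesized_sign}
            for p in m.paths
        ],
        "hoc_components": {k: list(v) for k, v in m.hoc_components.items()},
    }


def model_from_dict(d: dict) -> ModelDefinition:
    return ModelDefinition(
        latents=[
            LatentVariable(
                x["name"], x["role"], tuple(x.get("indicators", ())),
                x.get("order", "first"),
            )
            for x in d["latents"]
        ],
        paths=[
            StructuralPath(x["source"], x["target"], int(x.get("sign", 1)))
            for x in d["paths"]
        ],
        hoc_components={k: list(v) for k, v in d.get("hoc_components", {}).items()},
        scale=tuple(d.get("scale", (1, 10))),
    )


def model_to_yaml(m: ModelDefinition, path=None) -> str:
    text = yaml.safe_dump(model_to_dict(m), sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def model_from_yaml(src) -> ModelDefinition:
    """Load a model from a YAML string or file path."""
    import os

    if isinstance(src, str) and not os.path.exists(src) and "\n" in src:
        return model_from_dict(yaml.safe_load(src))
    if hasattr(src, "read"):
        return model_from_dict(yaml.safe_load(src))
    with open(src, "r", encoding="utf-8") as fh:
        return model_from_dict(yaml.safe_load(fh))
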