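"""Variable schema shared across samples, imputers and pipelines.

A schema maps each variable name to a :class:`VariableSchema` describing its
measurement kind.  ``binary`` variables take values in {0, 1}; ``categorical``
variables carry an explicit ordered tuple of levels (integer codes throughout
this package); ``continuous`` variables are real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VariableSchema:
    kind: str  # "binary" | "categorical" | "continuous"
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError("categorical variable needs at least 2 levels")

    @property
    def is_discrete(self) -> bool:
        return self.kind in ("binary", "categorical")

    def level_tuple(self) -> tuple:
        if self.kind == "binary":
            return (0, 1)
        return tuple(self.levels)


Schema = dict  # name -> VariableSchema; plain dict keeps insertion order


def schema_to_dict(schema: Schema) -> dict:
    """Serializable form of a schema (for YAML/JSON sidecars)."""
    return {
        name: {"kind": vs.kind, "levels": list(vs.levels)}
        for name, vs in schema.items()
    }


def schema_from_dict(d: dict) -> Schema:
    return {
        name: VariableSchema(spec["kind"], tuple(spec.get("levels", ())))
        for name, spec in d.items()
    }
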