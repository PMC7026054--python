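"""White-matter tract atlas.

The diffusion-MRI phenotypes are organised around a fixed probabilistic-tractography
atlas of 15 major white-matter tracts. Twelve tracts are bilateral (measured once per
hemisphere) and three are midline commissural/brainstem structures measured once
(forceps minor, forceps major, middle cerebellar peduncle), giving 27 tract variables
in total. The variables partition into three anatomical categories:

* association fibres   — 12 variables (6 bilateral tracts)
* thalamic radiations  —  6 variables (3 bilateral tracts)
* projection fibres    —  9 variables (3 bilateral + 3 unilateral tracts)

Each tract carries a fractional-anisotropy (FA) and a mean-diffusivity (MD) measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ASSOCIATION = "association"
THALAMIC = "thalamic"
PROJECTION = "projection"

CATEGORIES = (ASSOCIATION, THALAMIC, PROJECTION)

HEMISPHERES = ("left", "right")
NO_HEMISPHERE = "none"

MEASURES = ("FA", "MD")


@dataclass(frozen=True)
class Tract:
    tract_id: str
    name: str
    category: str
    bilateral: bool

    def variables(self) -> list[tuple[str, str]]:
        """(tract_id, hemisphere) variables this tract contributes."""
        if self.bilateral:
            return [(self.tract_id, h) for h in HEMISPHERES]
        return [(self.tract_id, NO_HEMISPHERE)]


@dataclass(frozen=True)
class TractAtlas:
    tracts: tuple[Tract, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [t.tract_id for t in self.tracts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate tract ids in atlas")
        for t in self.tracts:
            if t.category not in CATEGORIES:
                raise ValueError(f"unknown tract category: {t.category!r}")

    def variables(self, category: str | None = None) -> list[tuple[str, str]]:
        """All (tract_id, hemisphere) variables, optionally restricted to a category."""
        out: list[tuple[str, str]] = []
        for t in self.tracts:
            if category is None or t.category == category:
                out.extend(t.variables())
        return out

    def variable_names(self, category: str | None = None) -> list[str]:
        return [variable_name(t, h) for t, h in self.variables(category)]

    def category_sizes(self) -> dict[str, int]:
        """Number of tract variables per category."""
        return {c: len(self.variables(c)) for c in CATEGORIES}

    def n_variables(self) -> int:
        return len(self.variables())

    def get(self, tract_id: str) -> Tract:
        for t in self.tracts:
            if t.tract_id == tract_id:
                return t
        raise KeyError(f"tract {tract_id!r} not in atlas")

    @property
    def tract_ids(self) -> list[str]:
        return [t.tract_id for t in self.tracts]


def variable_name(tract_id: str, hemisphere: str) -> str:
    """Canonical column name for a (tract, hemisphere) variable."""
    if hemisphere == NO_HEMISPHERE:
        return tract_id
    return f"{tract_id}_{hemisphere}"


_TRACTS = (
    # association fibres: 6 bilateral tracts -> 12 variables
    Tract("ifof", "inferior fronto-occipital fasciculus", ASSOCIATION, True),
    Tract("ilf", "inferior longitudinal fasciculus", ASSOCIATION, True),
    Tract("slf", "superior longitudinal fasciculus", ASSOCIATION, True),
    Tract("unc", "uncinate fasciculus", ASSOCIATION, True),
    Tract("cing_g", "cingulum, cingulate gyrus part", ASSOCIATION, True),
    Tract("cing_ph", "cingulum, parahippocampal part", ASSOCIATION, True),
    # thalamic radiations: 3 bilateral tracts -> 6 variables
    Tract("atr", "anterior thalamic radiation", THALAMIC, True),
    Tract("str", "superior thalamic radiation", THALAMIC, True),
    Tract("ptr", "posterior thalamic radiation", THALAMIC, True),
    # projection fibres: 3 bilateral + 3 midline unilateral tracts -> 9 variables
    Tract("ar", "acoustic radiation", PROJECTION, True),
    Tract("cst", "corticospinal tract", PROJECTION, True),
    Tract("ml", "medial lemniscus", PROJECTION, True),
    Tract("fmin", "forceps minor", PROJECTION, False),
    Tract("fmaj", "forceps major", PROJECTION, False),
    Tract("mcp", "middle cerebellar peduncle", PROJECTION, False),
)


def make_tract_atlas() -> TractAtlas:
    """The fixed 27-variable tract atlas (12 association / 6 thalamic / 9 projection)."""
    return TractAtlas(tracts=_TRACTS)
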