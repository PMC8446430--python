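"""Preset immune-marker-combination panels.

Two panel sizes are used throughout: a compact 18-population panel for
three-way cohort comparisons and a 100-population panel for the in-depth
case-versus-control comparison. The 18-population preset below carries
functional annotations for the marker combinations repeatedly highlighted in
post-transplant immune-reconstitution work (activated T cells, naive/memory
helper and cytotoxic T subsets, activated B cells, NK subsets).

The 100-population preset extends the annotated core with systematically
generated marker combinations (base lineage gates crossed with
activation/memory modifier markers). It is a synthetic stand-in with
field-plausible identifiers: the full gating catalogue behind the original
100-subset panel is not public, and nothing downstream depends on the
identity of individual ids beyond uniqueness.
"""

from __future__ import annotations

from itertools import combinations

from .profiles import PopulationPanel

#: Annotated core panel (K = 18).
PANEL_18_ANNOTATIONS: dict[str, str] = {
    "CD3+": "Total T cells",
    "CD3+/HLA-DR+": "Activated T cells expressing the late activation marker HLA-DR",
    "CD3+/HLA-DR+/CD69+/CD134-": "Activated T cells with early marker CD69, lacking CD134",
    "CD3+/HLA-DR+/CD134+/CD69-": "Late-activated T cells with CD134, lacking CD69",
    "CD4+": "Total T helper cells",
    "CD4+/CD45RA+": "Naive T helper cells",
    "CD4+/CD45RO+": "Memory T helper cells",
    "CD8+": "Total cytotoxic T cells",
    "CD8+/CD45RA-": "Memory cytotoxic T cells",
    "CD8+/CD27-": "Effector cytotoxic T cells",
    "CD8+/CD25-": "Cytotoxic T cells lacking the intermediate activation marker CD25",
    "CD19+": "Total B cells",
    "CD19+/CD80+": "Activated B cells (CD80)",
    "CD19+/CD86+": "Activated B cells (CD86)",
    "CD3-/CD56+": "Total NK cells",
    "CD3-/CD56+/CD16+/CD134+": "Cytotoxic NK cells expressing marker of stimulation",
    "CD3-/CD56+/CD16+/CD107a/b+": "Cytotoxic NK cells expressing marker of degranulation",
    "CD3-/CD56+/CD16+/CD314+": "Cytotoxic NK cells expressing the activating receptor NKG2D",
}

#: Additional annotated combinations used by the 100-population panel
#: (memory/effector fine structure and further NK subsets).
_EXTRA_ANNOTATIONS: dict[str, str] = {
    "CD4+/CD27+": "Naive and memory T helper cells",
    "CD4+/CD27-": "Effector T helper cells",
    "CD4+/CD29-": "T helper cells lacking beta(1) integrin CD29",
    "CD4+/CD127+": "Naive, central-memory and effector-memory T helper cells",
    "CD4+/CD45RO-": "Non-memory T helper cells",
    "CD8+/CD45RO+": "Memory cytotoxic T cells",
    "CD8+/CD45RA-/CD29+": "Memory cytotoxic T cells",
    "CD8+/CD45RO+/CD29+": "Memory cytotoxic T cells",
    "CD8+/CD29+": "Memory cytotoxic T cells",
    "CD8+/CD127-": "Effector cytotoxic T cells",
    "CD27-/CD45RO+": "Central-memory and effector-memory lymphocytes",
    "CD3-/CD56+/CD16+": "Cytotoxic NK cells",
    "CD3-/CD56+/CD16+/CD159a+": "Cytotoxic NK cells expressing the inhibitory receptor NKG2A",
    "CD3-/CD56+/CD16-/CD63+": "Regulatory NK cells expressing the exocytosis marker CD63",
    "CD3-/CD56+/CD16-/CD314+": "Activated regulatory NK cells",
    "CD3-/CD56+/CD16+/CD117-": "Mature cytotoxic NK cells lacking CD117",
    "CD19+/CD5+": "B1-like B cells",
    "CD3+/CD86+": "Activated T cells (CD86)",
    "CD3+/CD134+": "T cells expressing the late activation marker CD134",
}


def panel_18() -> PopulationPanel:
    """The annotated 18-population preset."""
    return PopulationPanel(tuple(PANEL_18_ANNOTATIONS), dict(PANEL_18_ANNOTATIONS))


_BASES = ("CD3+", "CD4+", "CD8+", "CD19+", "CD3-/CD56+")
_MODIFIERS = ("CD25+", "CD27+", "CD28+", "CD38+", "CD57+", "CD62L+", "CD69+",
              "CD95+", "CD45RA+", "CD45RO+", "HLA-DR+", "CD127+")


def panel_100() -> PopulationPanel:
    """The 100-population preset: annotated core plus generated combinations.

    Deterministic: the annotated ids come first (stable order), then base
    lineage gates crossed with one or two modifier markers until K = 100.
    """
    ids = list(PANEL_18_ANNOTATIONS) + [
        i for i in _EXTRA_ANNOTATIONS if i not in PANEL_18_ANNOTATIONS
    ]
    seen = set(ids)
    for n_mod in (1, 2):
        for base in _BASES:
            for mods in combinations(_MODIFIERS, n_mod):
                cand = "/".join((base,) + mods)
                if cand not in seen:
                    seen.add(cand)
                    ids.append(cand)
                if len(ids) == 100:
                    annotations = {**PANEL_18_ANNOTATIONS, **_EXTRA_ANNOTATIONS}
                    return PopulationPanel(tuple(ids), annotations)
    raise RuntimeError("could not assemble 100 unique combinations")  # pragma: no cover


def preset(size: int) -> PopulationPanel:
    """Return the K=18 or K=100 preset panel."""
    if size == 18:
        return panel_18()
    if size == 100:
        return panel_100()
    raise ValueError(f"no preset panel of size {size}; available: 18, 100")
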