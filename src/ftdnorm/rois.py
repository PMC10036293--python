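"""Region-of-interest registry.

The analysis operates on summary measures of named brain regions: grey-matter
(GM) volumes of cortical and subcortical regions, and diffusion indices
(fractional anisotropy, FA; mean diffusivity, MD) of white-matter tracts.
The registry records every region the pipeline knows about, its tissue
category and which modalities it carries, and whether it takes part in the
default progression analysis (subfield-level regions — amygdala, hippocampus,
thalamus and hypothalamus subnuclei — are scoreable but the default
progression run uses only whole structures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

VOLUME = "volume"
FA = "FA"
MD = "MD"
MODALITIES = (VOLUME, FA, MD)

#: Modalities where disease lowers the measure (abnormal = lower tail).
LOWER_TAIL_MODALITIES = frozenset({VOLUME, FA})
#: Modalities where disease raises the measure (abnormal = upper tail).
UPPER_TAIL_MODALITIES = frozenset({MD})


@dataclass(frozen=True)
class ROI:
    """One named region with its tissue category and measured modalities."""

    name: str
    category: str  # cortical | subcortical | subfield | wm_tract | global
    modalities: tuple[str, ...]
    in_default_progression: bool = True
    parent: str | None = None  # whole structure a subfield belongs to


CORTICAL_ROIS = (
    "orbitofrontal",
    "dlpfc",
    "vmpfc",
    "motor",
    "insula",
    "temporal_pole",
    "dorsolateral_temporal",
    "medial_temporal",
    "cingulate",
    "sensory",
    "medial_parietal",
    "lateral_parietal",
    "occipital",
)

SUBCORTICAL_ROIS = (
    "nucleus_accumbens",
    "caudate",
    "putamen",
    "globus_pallidus",
    "basal_forebrain",
    "amygdala",
    "hippocampus",
    "thalamus",
    "hypothalamus",
)

# Subfield-level parcels, keyed by whole structure.
_SUBFIELDS = {
    "amygdala": (
        "lateral_nucleus",
        "basal_paralaminar_nucleus",
        "accessory_basal_nucleus",
        "cortico_amygdaloid_transition",
        "superficial_nuclei",
    ),
    "hippocampus": (
        "ca1",
        "ca2_ca3",
        "ca4",
        "dentate_gyrus",
        "subiculum",
        "presubiculum",
        "tail",
    ),
    "thalamus": (
        "anteroventral",
        "laterodorsal",
        "lateral_posterior",
        "ventral_anterior",
        "ventral_lateral_anterior",
        "ventral_lateral_posterior",
        "ventral_posterolateral",
        "ventromedial",
        "intralaminar",
        "midline",
        "mediodorsal",
        "lateral_geniculate",
        "medial_geniculate",
        "pulvinar",
    ),
    "hypothalamus": (
        "anterior_superior",
        "anterior_inferior",
        "superior_tuberal",
        "inferior_tuberal",
        "posterior",
    ),
}

# JHU white-matter tracts, bilateral averages, measured as FA and MD.
WM_TRACTS = (
    "uf",    # uncinate fasciculus
    "slf",   # superior longitudinal fasciculus
    "cingulum",
    "ss",    # sagittal stratum
    "ptr",   # posterior thalamic radiation
    "acr",   # anterior corona radiata
    "pcr",   # posterior corona radiata
    "scr",   # superior corona radiata
    "ec",    # external capsule
    "aic",   # anterior internal capsule
    "pic",   # posterior internal capsule
    "ric",   # retrolenticular internal capsule
    "gcc",   # genu of corpus callosum
    "bcc",   # body of corpus callosum
    "scc",   # splenium of corpus callosum
)


def _build_registry() -> dict[str, ROI]:
    reg: dict[str, ROI] = {}
    for name in CORTICAL_ROIS:
        reg[name] = ROI(name, "cortical", (VOLUME,))
    for name in SUBCORTICAL_ROIS:
        reg[name] = ROI(name, "subcortical", (VOLUME,))
    for parent, subs in _SUBFIELDS.items():
        for sub in subs:
            full = f"{parent}_{sub}"
            reg[full] = ROI(full, "subfield", (VOLUME,),
                            in_default_progression=False, parent=parent)
    for name in WM_TRACTS:
        reg[name] = ROI(name, "wm_tract", (FA, MD))
    reg["whole_brain"] = ROI("whole_brain", "global", (VOLUME,))
    return reg


REGISTRY: dict[str, ROI] = _build_registry()


def get_roi(name: str) -> ROI:
    """Look up a region by name, raising ``KeyError`` with the offender."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown ROI {name!r}") from None


def validate_roi_modality(name: str, modality: str) -> None:
    """Raise ``ValueError`` if the (ROI, modality) pair is not registered."""
    roi = get_roi(name)
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r} (expected one of {MODALITIES})")
    if modality not in roi.modalities:
        raise ValueError(f"ROI {name!r} does not carry modality {modality!r}")


def default_progression_rois() -> list[tuple[str, str]]:
    """(ROI, modality) pairs entering the default progression analysis.

    Whole cortical/subcortical structures and WM tracts only; subfields are
    excluded by default.
    """
    pairs: list[tuple[str, str]] = []
    for roi in REGISTRY.values():
        if not roi.in_default_progression:
            continue
        pairs.extend((roi.name, m) for m in roi.modalities)
    return pairs


def default_map_rois() -> list[tuple[str, str]]:
    """All registered (ROI, modality) pairs, subfields included."""
    pairs: list[tuple[str, str]] = []
    for roi in REGISTRY.values():
        pairs.extend((roi.name, m) for m in roi.modalities)
    return pairs
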