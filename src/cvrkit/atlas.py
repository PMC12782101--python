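"""Region atlas: the candidate volumes a composite value ratio may draw on.

The default atlas holds 52 bilateral structures: the 34 Desikan-Killiany
cortical parcels plus 18 subcortical, ventricular and corpus-callosum
structures. Intracranial volume (ICV) and whole-brain volume are carried in
volume tables as normalisers for the traditional biomarkers but are never
candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Desikan-Killiany cortical parcels (bilateral, FreeSurfer naming).
DK_CORTICAL = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Subcortical, ventricular and corpus-callosum structures.
SUBCORTICAL = (
    "lateral_ventricle",
    "inf_lat_vent",
    "hippocampus",
    "amygdala",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens_area",
    "ventraldc",
    "brainstem",
    "choroid_plexus",
    "cerebellum_cortex",
    "cc_anterior",
    "cc_mid_anterior",
    "cc_central",
    "cc_mid_posterior",
    "cc_posterior",
)


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered collection of candidate region names plus the ICV column name.

    Parameters
    ----------
    region_names
        Unique, ordered region identifiers (genome positions follow this
        order).
    icv_name
        Name of the intracranial-volume column; must not be a region.
    """

    region_names: tuple[str, ...] = field(default=DK_CORTICAL + SUBCORTICAL)
    icv_name: str = "icv"

    def __post_init__(self) -> None:
        names = tuple(self.region_names)
        object.__setattr__(self, "region_names", names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dupes}")
        if self.icv_name in names:
            raise ValueError(
                f"icv_name {self.icv_name!r} must not appear in region_names"
            )

    def __len__(self) -> int:
        return len(self.region_names)

    def __contains__(self, name: str) -> bool:
        return name in self.region_names

    def index(self, name: str) -> int:
        return self.region_names.index(name)

    def subset(self, names) -> "RegionAtlas":
        """Atlas restricted to ``names`` (kept in original atlas order)."""
        keep = tuple(n for n in self.region_names if n in set(names))
        missing = set(names) - set(keep)
        if missing:
            raise KeyError(f"unknown regions: {sorted(missing)}")
        return RegionAtlas(region_names=keep, icv_name=self.icv_name)


DEFAULT_ATLAS = RegionAtlas()

assert len(DEFAULT_ATLAS) == 52
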