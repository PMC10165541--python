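"""Nervous-system compartment taxonomy.

Every compartment label maps to exactly one cell class (neuron, glia or
muscle) and one subregion (soma or periphery).  The default taxonomy covers
the larval CNS and neuromuscular junction compartments scored in the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NEURON = "neuron"
GLIA = "glia"
MUSCLE = "muscle"
SOMA = "soma"
PERIPHERY = "periphery"

CELL_CLASSES = (NEURON, GLIA, MUSCLE)
SUBREGIONS = (SOMA, PERIPHERY)

#: label -> (cell_class, subregion)
DEFAULT_LABELS: dict[str, tuple[str, str]] = {
    "central_brain_soma": (NEURON, SOMA),
    "neuroblast_lineage": (NEURON, SOMA),
    "mushroom_body_neuropil": (NEURON, PERIPHERY),
    "optic_lobe_neuropil": (NEURON, PERIPHERY),
    "vnc_neuropil": (NEURON, PERIPHERY),
    "segmental_nerve": (NEURON, PERIPHERY),
    "nmj_axon_terminal": (NEURON, PERIPHERY),
    "psd": (MUSCLE, PERIPHERY),
    "muscle_cytoplasm": (MUSCLE, SOMA),
    "muscle_nucleus": (MUSCLE, SOMA),
    "glial_process_cortex": (GLIA, PERIPHERY),
    "glial_process_neuropil": (GLIA, PERIPHERY),
    "glial_process_nmj": (GLIA, PERIPHERY),
}

#: compartments counted as "periphery of neurons" for headline statistics
DEFAULT_PERIPHERAL_NEURON_LABELS = (
    "mushroom_body_neuropil",
    "optic_lobe_neuropil",
    "vnc_neuropil",
    "segmental_nerve",
    "nmj_axon_terminal",
)

DEFAULT_PERIPHERAL_GLIA_LABELS = (
    "glial_process_cortex",
    "glial_process_neuropil",
    "glial_process_nmj",
)


@dataclass(frozen=True)
class CompartmentTaxonomy:
    """Mapping of compartment labels to cell class and subregion."""

    cell_class_of: dict[str, str] = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_LABELS.items()}
    )
    subregion_of: dict[str, str] = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_LABELS.items()}
    )

    def __post_init__(self) -> None:
        if set(self.cell_class_of) != set(self.subregion_of):
            raise ValueError("cell_class_of and subregion_of must share labels")
        for label in self.cell_class_of:
            if self.cell_class_of[label] not in CELL_CLASSES:
                raise ValueError(f"unknown cell class for {label!r}")
            if self.subregion_of[label] not in SUBREGIONS:
                raise ValueError(f"unknown subregion for {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.cell_class_of)

    def labels_of_class(self, cell_class: str) -> tuple[str, ...]:
        return tuple(
            lab for lab, cls in self.cell_class_of.items() if cls == cell_class
        )

    def labels_of_subregion(self, cell_class: str, subregion: str) -> tuple[str, ...]:
        return tuple(
            lab
            for lab in self.labels_of_class(cell_class)
            if self.subregion_of[lab] == subregion
        )

    def cell_classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for cls in self.cell_class_of.values():
            if cls not in seen:
                seen.append(cls)
        return tuple(seen)


DEFAULT_TAXONOMY = CompartmentTaxonomy()
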