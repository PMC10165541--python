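"""Deterministic benchmark tables with exact, configurable marginal tallies.

Unlike :mod:`fishscreen.synthetic`, which draws from stochastic models,
these builders construct annotation tables and neuroblast panels whose
marginal counts are exact by construction, so screen-level summaries can be
checked against known tallies.  Default counts match the headline tallies of
the 200-gene reference screen this pipeline was built for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fishscreen.taxonomy import DEFAULT_TAXONOMY

#: compartments scored in the fixture, one tissue
FIXTURE_COMPARTMENTS = DEFAULT_TAXONOMY.labels
FIXTURE_TISSUE = "nervous_system"


def build_screen_annotation_table(
    n_genes: int = 200,
    n_discordant: int = 195,
    n_mb_protein: int = 94,
    n_mb_protein_with_mrna: int = 30,
    n_mb_mrna_total: int = 67,
    n_mb_ol_mrna_overlap: int = 28,
    n_nmj_glia: int = 19,
    n_homozygous_viable: int = 131,
    n_annotators: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unanimous three-annotator table with exact headline marginals.

    Gene blocks (by index) realize the requested counts:

    * genes < ``n_mb_protein`` carry mushroom-body protein, the first
      ``n_mb_protein_with_mrna`` of them also mushroom-body mRNA;
    * the mushroom-body mRNA set is topped up to ``n_mb_mrna_total`` with
      mRNA-only genes; its first ``n_mb_ol_mrna_overlap`` members also carry
      optic-lobe mRNA;
    * genes < ``n_nmj_glia`` express in NMJ glial processes;
    * genes < ``n_discordant`` carry an mRNA-without-protein call in the VNC
      neuropil, the rest are concordant everywhere;
    * every gene expresses concordantly in the central-brain soma, so each
      gene is scored in every compartment.

    Returns (annotation table, per-gene metadata with homozygous_viable).
    """
    if not (
        n_mb_protein_with_mrna <= min(n_mb_protein, n_mb_mrna_total)
        and n_mb_ol_mrna_overlap <= n_mb_mrna_total
        and max(
            n_discordant, n_mb_protein, n_nmj_glia, n_homozygous_viable,
            n_mb_protein + (n_mb_mrna_total - n_mb_protein_with_mrna),
        )
        <= n_genes
    ):
        raise ValueError("fixture marginals are mutually inconsistent")

    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    mb_mrna_only = range(
        n_mb_protein, n_mb_protein + (n_mb_mrna_total - n_mb_protein_with_mrna)
    )

    def truth(i: int, comp: str) -> tuple[bool, bool]:
        mrna = protein = False
        if comp == "central_brain_soma":
            mrna = protein = True
        elif comp == "mushroom_body_neuropil":
            protein = i < n_mb_protein
            mrna = i < n_mb_protein_with_mrna or i in mb_mrna_only
        elif comp == "optic_lobe_neuropil":
            # overlap counts mRNA only; keep protein co-present so the
            # compartment itself stays concordant
            mrna = protein = _mb_mrna_rank(
                i, n_mb_protein, n_mb_protein_with_mrna, mb_mrna_only
            ) < n_mb_ol_mrna_overlap
        elif comp == "glial_process_nmj":
            mrna = protein = i < n_nmj_glia
        elif comp == "vnc_neuropil":
            mrna = i < n_discordant
            protein = False
        return mrna, protein

    rows = []
    annotators = [f"annotator_{chr(ord('A') + a)}" for a in range(n_annotators)]
    for i, gid in enumerate(genes):
        for comp in FIXTURE_COMPARTMENTS:
            mrna, protein = truth(i, comp)
            for ann in annotators:
                rows.append(
                    dict(
                        gene_id=gid, tissue=FIXTURE_TISSUE, compartment=comp,
                        annotator=ann, mrna_present=mrna, protein_present=protein,
                    )
                )
    table = pd.DataFrame(rows)
    metadata = pd.DataFrame(
        dict(gene_id=genes, homozygous_viable=np.arange(n_genes) < n_homozygous_viable)
    )
    return table, metadata


def _mb_mrna_rank(i, n_mb_protein, n_with_mrna, mb_mrna_only) -> int:
    """Rank of gene i within the mushroom-body mRNA set (large if absent)."""
    if i < n_with_mrna:
        return i
    if i in mb_mrna_only:
        return n_with_mrna + (i - n_mb_protein)
    return 10**9


def build_neuroblast_panels(
    n_not_detected: int = 43,
    n_homogeneous: int = 114,
    n_transcriptional: int = 31,
    n_posttranscriptional: int = 12,
    n_cells: int = 20,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Noiseless per-cell panels with exact per-class gene counts."""
    rng = np.random.default_rng(seed)
    classes = (
        ["not_detected"] * n_not_detected
        + ["homogeneous"] * n_homogeneous
        + ["cell_specific_transcriptional"] * n_transcriptional
        + ["cell_specific_posttranscriptional"] * n_posttranscriptional
    )
    panels: dict[str, pd.DataFrame] = {}
    labels: dict[str, str] = {}
    for g, cls in enumerate(classes):
        gid = f"gene_{g:04d}"
        labels[gid] = cls
        mrna_on = np.zeros(n_cells, dtype=bool)
        prot_on = np.zeros(n_cells, dtype=bool)
        if cls == "homogeneous":
            mrna_on[:] = prot_on[:] = True
        elif cls == "cell_specific_transcriptional":
            k = n_cells // 2
            mrna_on[:k] = prot_on[:k] = True
        elif cls == "cell_specific_posttranscriptional":
            mrna_on[:] = True
            prot_on[: max(2, n_cells // 5)] = True
        mrna_count = np.where(mrna_on, rng.poisson(8, n_cells) + 2, 0)
        protein = np.where(
            prot_on,
            rng.normal(100.0, 10.0, n_cells),
            rng.normal(10.0, 2.0, n_cells),
        )
        panels[gid] = pd.DataFrame(
            dict(
                cell_id=[f"cell_{i:03d}" for i in range(n_cells)],
                cell_type=["neuroblast"] + ["GMC"] * 3
                + ["progeny"] * (n_cells - 4),
                mrna_count=mrna_count,
                protein_intensity=protein,
                has_transcription_focus=mrna_on,
            )
        )
    return panels, labels
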