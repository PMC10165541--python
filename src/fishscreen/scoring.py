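"""Majority-vote aggregation and mRNA/protein discordance classification.

Consumes long-format annotator tables (gene_id, tissue, compartment,
annotator, mrna_present, protein_present with values True/False/NA) and
produces resolved per-compartment calls, per-gene discordance profiles over
the compartment taxonomy, screen-level tabulations (four-category splits,
UpSet intersection counts, headline percentages), neuroblast expression
pattern classes and genome-scale extrapolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from fishscreen.taxonomy import (
    DEFAULT_PERIPHERAL_GLIA_LABELS,
    DEFAULT_PERIPHERAL_NEURON_LABELS,
    GLIA,
    NEURON,
    PERIPHERY,
    SOMA,
    CompartmentTaxonomy,
)

KEY = ["gene_id", "tissue", "compartment"]

UNANIMOUS = "unanimous"
MAJORITY = "majority"
UNRESOLVED = "escalated_unresolved"

CONCORDANT = "concordant"
DISCORDANT = "discordant"


# --------------------------------------------------------------------------
# majority vote
# --------------------------------------------------------------------------


def _vote(values) -> tuple[object, str]:
    """Strict majority of non-NA votes; NA votes are ignored.

    Returns (call, resolution) where call is True/False or pd.NA when no
    strict majority exists among the non-NA votes.
    """
    non_na = [bool(v) for v in values if not pd.isna(v)]
    n_true = sum(non_na)
    n_false = len(non_na) - n_true
    if n_true == n_false:
        return pd.NA, UNRESOLVED
    call = n_true > n_false
    if len(non_na) == len(values) and (n_true == 0 or n_false == 0):
        return call, UNANIMOUS
    return call, MAJORITY


def aggregate_majority(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate annotator votes per (gene, tissue, compartment).

    Requires at least three annotators per key (raises naming the offending
    key otherwise).  Returns (calls, conflicts): ``calls`` holds one row per
    key with mrna / protein calls and their resolution; keys without a
    strict majority carry resolution ``escalated_unresolved`` and appear in
    the ``conflicts`` report for fourth-expert escalation.
    """
    required = set(KEY + ["annotator", "mrna_present", "protein_present"])
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=KEY + ["annotator"])
    if dup.any():
        raise ValueError("duplicate (gene, tissue, compartment, annotator) rows")
    rows = []
    for key, grp in table.groupby(KEY, sort=True):
        if len(grp) < 3:
            raise ValueError(
                f"key {key} has only {len(grp)} annotators; >= 3 required"
            )
        mrna, mrna_res = _vote(grp["mrna_present"].tolist())
        protein, prot_res = _vote(grp["protein_present"].tolist())
        if UNRESOLVED in (mrna_res, prot_res):
            resolution = UNRESOLVED
        elif MAJORITY in (mrna_res, prot_res):
            resolution = MAJORITY
        else:
            resolution = UNANIMOUS
        rows.append(
            dict(
                gene_id=key[0], tissue=key[1], compartment=key[2],
                mrna=mrna, protein=protein,
                mrna_resolution=mrna_res, protein_resolution=prot_res,
                resolution=resolution,
            )
        )
    calls = pd.DataFrame(rows)
    conflicts = calls[calls["resolution"] == UNRESOLVED].reset_index(drop=True)
    return calls, conflicts


def resolved_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Calls excluding unresolved (escalated) keys."""
    return calls[calls["resolution"] != UNRESOLVED].reset_index(drop=True)


@dataclass
class AgreementReport:
    per_annotator: pd.DataFrame  # annotator, n_votes, n_disagreements, rate
    per_question: pd.DataFrame  # key columns + n_conflicting_votes
    overall_disagreement_rate: float


def annotator_agreement(
    table: pd.DataFrame, calls: pd.DataFrame | None = None
) -> AgreementReport:
    """Per-annotator disagreement rate against the majority consensus."""
    if calls is None:
        calls, _ = aggregate_majority(table)
    consensus = resolved_calls(calls).set_index(KEY)
    merged = table.join(consensus[["mrna", "protein"]], on=KEY, how="inner")
    stats = []
    total_votes = 0
    total_dis = 0
    for ann, grp in merged.groupby("annotator", sort=True):
        n_votes = 0
        n_dis = 0
        for col, cons_col in (("mrna_present", "mrna"), ("protein_present", "protein")):
            valid = grp[col].notna() & grp[cons_col].notna()
            n_votes += int(valid.sum())
            n_dis += int(
                (grp.loc[valid, col].astype(bool)
                 != grp.loc[valid, cons_col].astype(bool)).sum()
            )
        stats.append(
            dict(
                annotator=ann, n_votes=n_votes, n_disagreements=n_dis,
                disagreement_rate=n_dis / n_votes if n_votes else np.nan,
            )
        )
        total_votes += n_votes
        total_dis += n_dis
    per_q = []
    for key, grp in merged.groupby(KEY, sort=True):
        n_conf = 0
        for col, cons_col in (("mrna_present", "mrna"), ("protein_present", "protein")):
            valid = grp[col].notna() & grp[cons_col].notna()
            n_conf += int(
                (grp.loc[valid, col].astype(bool)
                 != grp.loc[valid, cons_col].astype(bool)).sum()
            )
        if n_conf:
            per_q.append(
                dict(zip(KEY, key)) | dict(n_conflicting_votes=n_conf)
            )
    return AgreementReport(
        per_annotator=pd.DataFrame(stats),
        per_question=pd.DataFrame(
            per_q, columns=KEY + ["n_conflicting_votes"]
        ),
        overall_disagreement_rate=total_dis / total_votes if total_votes else np.nan,
    )


# --------------------------------------------------------------------------
# discordance classification
# --------------------------------------------------------------------------


def classify_class_pattern(
    mrna_soma: bool, mrna_periph: bool, protein_soma: bool, protein_periph: bool,
    soma_scored: bool = True, periph_scored: bool = True,
) -> tuple[bool, bool]:
    """(intercellular, intracellular) evidence for one cell class.

    Intercellular: one molecule present somewhere in the class while the
    other is absent everywhere in the class.  Intracellular: both molecules
    present in the class but with different soma/periphery presence
    patterns.
    """
    m_any = (mrna_soma and soma_scored) or (mrna_periph and periph_scored)
    p_any = (protein_soma and soma_scored) or (protein_periph and periph_scored)
    inter = m_any != p_any
    intra = False
    if m_any and p_any:
        m_pat = (mrna_soma and soma_scored, mrna_periph and periph_scored)
        p_pat = (protein_soma and soma_scored, protein_periph and periph_scored)
        intra = m_pat != p_pat
    return inter, intra


def classify_discordance(
    calls: pd.DataFrame,
    taxonomy: CompartmentTaxonomy | None = None,
    peripheral_neuron_labels=DEFAULT_PERIPHERAL_NEURON_LABELS,
    peripheral_glia_labels=DEFAULT_PERIPHERAL_GLIA_LABELS,
) -> pd.DataFrame:
    """Per gene x tissue discordance events.

    Status is discordant iff any scored compartment shows mRNA XOR protein.
    Evidence types are evaluated per cell class at soma/periphery
    granularity; a compartment-level mismatch that aggregates away at that
    granularity (two populations within one subregion differing) is counted
    as intercellular evidence, since distinct compartments hold distinct
    cells.  Tissues with no scored compartments are omitted.
    """
    taxonomy = taxonomy or CompartmentTaxonomy()
    calls = resolved_calls(calls)
    calls = calls[calls["compartment"].isin(taxonomy.labels)]
    rows = []
    for (gene, tissue), grp in calls.groupby(["gene_id", "tissue"], sort=True):
        if grp.empty:
            continue
        comp = dict(
            zip(
                grp["compartment"],
                zip(grp["mrna"].astype(bool), grp["protein"].astype(bool)),
            )
        )
        xor = any(m != p for m, p in comp.values())
        inter = intra = False
        for cls in taxonomy.cell_classes():
            members = [c for c in comp if taxonomy.cell_class_of[c] == cls]
            if not members:
                continue
            soma_members = [c for c in members if taxonomy.subregion_of[c] == SOMA]
            per_members = [c for c in members if taxonomy.subregion_of[c] == PERIPHERY]
            m_soma = any(comp[c][0] for c in soma_members)
            m_per = any(comp[c][0] for c in per_members)
            p_soma = any(comp[c][1] for c in soma_members)
            p_per = any(comp[c][1] for c in per_members)
            c_inter, c_intra = classify_class_pattern(
                m_soma, m_per, p_soma, p_per,
                soma_scored=bool(soma_members),
                periph_scored=bool(per_members),
            )
            class_xor = any(comp[c][0] != comp[c][1] for c in members)
            if class_xor and not (c_inter or c_intra):
                c_inter = True  # between-population mismatch within a subregion
            inter |= c_inter
            intra |= c_intra
        status = DISCORDANT if xor else CONCORDANT
        if status == CONCORDANT:
            dtype = "none"
        elif inter and intra:
            dtype = "both"
        elif inter:
            dtype = "intercellular"
        else:
            dtype = "intracellular"
        periph_neuron = any(
            comp[c][0] for c in comp if c in peripheral_neuron_labels
        )
        periph_glia = any(
            comp[c][0] for c in comp if c in peripheral_glia_labels
        )
        rows.append(
            dict(
                gene_id=gene, tissue=tissue, status=status,
                discordance_type=dtype,
                intercellular=inter, intracellular=intra,
                peripheral_mrna_neuron=periph_neuron,
                peripheral_mrna_glia=periph_glia,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tissue", "status", "discordance_type",
            "intercellular", "intracellular",
            "peripheral_mrna_neuron", "peripheral_mrna_glia",
        ],
    )


def gene_discordance_profiles(events: pd.DataFrame) -> pd.DataFrame:
    """Roll gene x tissue events up to one row per gene."""
    rows = []
    for gene, grp in events.groupby("gene_id", sort=True):
        inter = bool(grp["intercellular"].any())
        intra = bool(grp["intracellular"].any())
        any_disc = bool((grp["status"] == DISCORDANT).any())
        if not any_disc:
            dtype = "none"
        elif inter and intra:
            dtype = "both"
        elif inter:
            dtype = "intercellular"
        else:
            dtype = "intracellular"
        rows.append(
            dict(
                gene_id=gene,
                n_tissues=len(grp),
                n_discordant_tissues=int((grp["status"] == DISCORDANT).sum()),
                any_discordance=any_disc,
                discordance_type=dtype,
                peripheral_mrna_neuron=bool(grp["peripheral_mrna_neuron"].any()),
                peripheral_mrna_glia=bool(grp["peripheral_mrna_glia"].any()),
            )
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# screen tabulation
# --------------------------------------------------------------------------

FOUR_CATEGORIES = ("both", "mrna_only", "protein_only", "neither")


@dataclass
class ScreenSummary:
    per_compartment: pd.DataFrame
    headline: dict = field(default_factory=dict)


def tabulate_expression(
    calls: pd.DataFrame,
    events: pd.DataFrame | None = None,
    taxonomy: CompartmentTaxonomy | None = None,
) -> ScreenSummary:
    """Four-category split per compartment plus headline scalars.

    Per compartment the categories both / mRNA only / protein only / neither
    are reported as counts and percentages summing to 100.  Headline scalars
    cover any-compartment discordance, peripheral mRNA in neurons and glia,
    and inter/intracellular event and gene shares.
    """
    calls = resolved_calls(calls)
    rows = []
    for (tissue, comp), grp in calls.groupby(["tissue", "compartment"], sort=True):
        m = grp["mrna"].astype(bool).to_numpy()
        p = grp["protein"].astype(bool).to_numpy()
        n = len(grp)
        counts = {
            "both": int((m & p).sum()),
            "mrna_only": int((m & ~p).sum()),
            "protein_only": int((~m & p).sum()),
            "neither": int((~m & ~p).sum()),
        }
        row = dict(tissue=tissue, compartment=comp, n_genes=n)
        for cat in FOUR_CATEGORIES:
            row[f"n_{cat}"] = counts[cat]
            row[f"pct_{cat}"] = 100.0 * counts[cat] / n if n else np.nan
        rows.append(row)
    per_comp = pd.DataFrame(rows)

    headline: dict = {}
    if events is None:
        events = classify_discordance(calls, taxonomy)
    profiles = gene_discordance_profiles(events)
    n_genes = len(profiles)
    headline["n_genes"] = n_genes
    if n_genes:
        headline["any_discordance_percent"] = (
            100.0 * profiles["any_discordance"].sum() / n_genes
        )
        headline["peripheral_mrna_neuron_percent"] = (
            100.0 * profiles["peripheral_mrna_neuron"].sum() / n_genes
        )
        headline["peripheral_mrna_glia_percent"] = (
            100.0 * profiles["peripheral_mrna_glia"].sum() / n_genes
        )
    disc_events = events[events["status"] == DISCORDANT]
    n_inter = int(disc_events["intercellular"].sum())
    n_intra = int(disc_events["intracellular"].sum())
    total = n_inter + n_intra
    headline["n_discordant_events"] = len(disc_events)
    if total:
        headline["intercellular_share_events_percent"] = 100.0 * n_inter / total
        headline["intracellular_share_events_percent"] = 100.0 * n_intra / total
    gp = profiles[profiles["any_discordance"]]
    g_inter = int(gp["discordance_type"].isin(["intercellular", "both"]).sum())
    g_intra = int(gp["discordance_type"].isin(["intracellular", "both"]).sum())
    g_total = g_inter + g_intra
    if g_total:
        headline["intercellular_share_genes_percent"] = 100.0 * g_inter / g_total
        headline["intracellular_share_genes_percent"] = 100.0 * g_intra / g_total
    return ScreenSummary(per_compartment=per_comp, headline=headline)


def upset_counts(
    calls: pd.DataFrame, molecule: str = "mrna"
) -> tuple[pd.DataFrame, pd.Series]:
    """Exact compartment-membership pattern counts for one molecule.

    Returns (pattern table, per-compartment marginal totals).  Pattern rows
    are sorted by count descending then pattern; the all-absent pattern is
    included when genes exhibit it.
    """
    if molecule not in ("mrna", "protein"):
        raise ValueError("molecule must be 'mrna' or 'protein'")
    calls = resolved_calls(calls)
    membership = (
        calls.assign(value=calls[molecule].astype(bool))
        .pivot_table(
            index="gene_id", columns="compartment", values="value",
            aggfunc="max", fill_value=False,
        )
        .astype(bool)
    )
    compartments = list(membership.columns)
    patterns = membership.groupby(compartments, sort=False).size()
    rows = []
    for pattern, count in patterns.items():
        if len(compartments) == 1:
            pattern = (pattern,)
        rows.append(dict(zip(compartments, pattern)) | dict(n_genes=int(count)))
    table = pd.DataFrame(rows).sort_values(
        ["n_genes"] + compartments, ascending=False
    ).reset_index(drop=True)
    marginals = membership.sum(axis=0)
    return table, marginals


def enumerate_upset_oracle(membership: pd.DataFrame) -> dict[tuple, int]:
    """Brute-force pattern counts over all 2^k patterns (testing aid)."""
    compartments = list(membership.columns)
    counts = {}
    for pattern in itertools.product([False, True], repeat=len(compartments)):
        n = int(
            (membership[compartments] == pd.Series(pattern, index=compartments))
            .all(axis=1)
            .sum()
        )
        if n:
            counts[pattern] = n
    return counts


# --------------------------------------------------------------------------
# neuroblast expression patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuroblastParams:
    mrna_floor: int = 2  # single molecules per cell
    protein_background_mean: float = 10.0
    protein_background_sd: float = 2.0
    protein_sigma_factor: float = 3.0
    high_fraction: float = 0.9
    not_detected_max_fraction: float = 0.1
    agreement_threshold: float = 0.8

    @property
    def protein_floor(self) -> float:
        return (
            self.protein_background_mean
            + self.protein_sigma_factor * self.protein_background_sd
        )


@dataclass
class NeuroblastPattern:
    gene_id: str
    pattern_class: str
    mrna_fraction: float
    protein_fraction: float
    presence_agreement: float
    n_cells: int


def classify_neuroblast_pattern(
    per_cell: pd.DataFrame,
    params: NeuroblastParams | None = None,
    gene_id: str = "",
) -> NeuroblastPattern:
    """Classify one gene's lineage expression pattern.

    Per-cell presence uses detection floors (>= ``mrna_floor`` molecules or a
    transcription focus for mRNA; intensity above background + k robust
    sigmas for protein).  not_detected: both expressing fractions at or
    below ``not_detected_max_fraction``; homogeneous: both at or above
    ``high_fraction``; otherwise cell-specific, split transcriptional vs
    post-transcriptional by the fraction of cells whose mRNA and protein
    presence agree.
    """
    params = params or NeuroblastParams()
    if len(per_cell) < 5:
        raise ValueError("need >= 5 cells per lineage")
    mrna_on = (per_cell["mrna_count"].to_numpy() >= params.mrna_floor) | (
        per_cell.get(
            "has_transcription_focus", pd.Series(False, index=per_cell.index)
        )
        .to_numpy()
        .astype(bool)
    )
    prot_on = per_cell["protein_intensity"].to_numpy() > params.protein_floor
    n = len(per_cell)
    m_frac = float(mrna_on.mean())
    p_frac = float(prot_on.mean())
    agreement = float((mrna_on == prot_on).mean())
    if (
        m_frac <= params.not_detected_max_fraction
        and p_frac <= params.not_detected_max_fraction
    ):
        cls = "not_detected"
    elif m_frac >= params.high_fraction and p_frac >= params.high_fraction:
        cls = "homogeneous"
    elif agreement >= params.agreement_threshold:
        cls = "cell_specific_transcriptional"
    else:
        cls = "cell_specific_posttranscriptional"
    return NeuroblastPattern(
        gene_id=gene_id, pattern_class=cls,
        mrna_fraction=m_frac, protein_fraction=p_frac,
        presence_agreement=agreement, n_cells=n,
    )


def classify_neuroblast_panel(
    panels: dict[str, pd.DataFrame],
    params: NeuroblastParams | None = None,
) -> pd.DataFrame:
    rows = [
        vars(classify_neuroblast_pattern(df, params, gene_id=gid))
        for gid, df in panels.items()
    ]
    return pd.DataFrame(rows)


def summarize_neuroblast_classes(classes: pd.Series | list) -> dict:
    """Fig 4-style shares: class percentages plus the split of the
    cell-specific set into correlated vs discordant."""
    s = pd.Series(list(classes))
    n = len(s)
    counts = s.value_counts().to_dict()
    n_trans = counts.get("cell_specific_transcriptional", 0)
    n_post = counts.get("cell_specific_posttranscriptional", 0)
    n_specific = n_trans + n_post
    out = dict(
        n_genes=n,
        n_cell_specific=n_specific,
        n_homogeneous=counts.get("homogeneous", 0),
        n_not_detected=counts.get("not_detected", 0),
        cell_specific_percent=100.0 * n_specific / n if n else np.nan,
        homogeneous_percent=100.0 * counts.get("homogeneous", 0) / n if n else np.nan,
        not_detected_percent=100.0 * counts.get("not_detected", 0) / n if n else np.nan,
    )
    if n_specific:
        out["correlated_percent_of_specific"] = 100.0 * n_trans / n_specific
        out["discordant_percent_of_specific"] = 100.0 * n_post / n_specific
        out["n_correlated"] = n_trans
        out["n_discordant"] = n_post
    return out


# --------------------------------------------------------------------------
# genome extrapolation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeExtrapolation:
    k: int
    n: int
    genome_protein_coding: int
    estimate: float
    lower: float
    upper: float

    @property
    def at_least(self) -> float:
        return self.lower


def extrapolate_genome(
    k: int, n: int, genome_protein_coding: int = 13_900, confidence: float = 0.95
) -> GenomeExtrapolation:
    """Scale an observed pattern fraction to the genome with a Wilson bound.

    The headline claim is one-sided ("at least this many genes"), so the
    reported lower bound is the one-sided Wilson bound at ``confidence``
    (the upper bound is its one-sided counterpart).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if genome_protein_coding <= 0:
        raise ValueError("genome_protein_coding must be positive")
    alpha_two_sided = 2.0 * (1.0 - confidence)
    lo, hi = proportion_confint(k, n, alpha=alpha_two_sided, method="wilson")
    return GenomeExtrapolation(
        k=k, n=n, genome_protein_coding=genome_protein_coding,
        estimate=genome_protein_coding * k / n,
        lower=float(genome_protein_coding * lo),
        upper=float(genome_protein_coding * hi),
    )


# --------------------------------------------------------------------------
# MDV-style flat export
# --------------------------------------------------------------------------


def export_mdv(
    calls: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    gene_metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One row per gene: per-compartment mRNA/protein calls, discordance
    fields and any free metadata columns; returns (table, JSON schema)."""
    calls = resolved_calls(calls)
    wide_m = calls.pivot_table(
        index="gene_id", columns="compartment", values="mrna",
        aggfunc="max",
    )
    wide_p = calls.pivot_table(
        index="gene_id", columns="compartment", values="protein",
        aggfunc="max",
    )
    wide_m.columns = [f"mrna__{c}" for c in wide_m.columns]
    wide_p.columns = [f"protein__{c}" for c in wide_p.columns]
    out = wide_m.join(wide_p)
    if profiles is not None:
        out = out.join(profiles.set_index("gene_id"))
    if gene_metadata is not None:
        out = out.join(gene_metadata.set_index("gene_id"))
    out = out.reset_index()
    schema = {
        "columns": [
            {"name": c, "dtype": str(out[c].dtype)} for c in out.columns
        ],
        "n_rows": len(out),
    }
    return out, schema
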