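"""End-to-end characterization of MT sequences and cohort aggregates.

Each record runs through: ORF finding, translation under the configured
genetic code, cysteine-cluster profiling, subfamily calling, grammar
parsing (modules for CdMTs, repeats for CuMTs), glutamine codon tallying,
theoretical metal capacity, residue composition and UTR motif scanning.
Per-sequence failures are recorded and skipped, never aborting the batch,
and every printed aggregate is recomputable from the per-sequence rows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import cyspattern, gencode, metal_capacity, modules_grammar, utr_motifs
from .dup_scan import AlignmentParams
from .seq_io import SequenceRecord


@dataclass
class RunConfig:
    genetic_code: str = "ciliate"
    min_orf: int = 60
    threshold_cd: float = 0.25
    threshold_cu: float = 0.50
    cu_max_triple: float = 0.05
    module_config: modules_grammar.ModuleConfig = field(
        default_factory=modules_grammar.ModuleConfig)
    motifs: tuple = utr_motifs.DEFAULT_MOTIFS
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    force_subfamily: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "module_config" in kwargs:
            kwargs["module_config"] = modules_grammar.ModuleConfig(
                **kwargs["module_config"])
        if "alignment" in kwargs:
            kwargs["alignment"] = AlignmentParams(**kwargs["alignment"])
        if "motifs" in kwargs:
            kwargs["motifs"] = tuple(
                utr_motifs.MotifDef(**m) for m in kwargs["motifs"])
        return cls(**kwargs)


@dataclass
class SequenceReport:
    seq_id: str
    subfamily: str
    profile: cyspattern.ClusterProfile
    capacity: metal_capacity.CapacityEstimate
    composition: gencode.CompositionStats
    protein: str
    modularity: modules_grammar.ModularityResult | None = None
    modules: list = field(default_factory=list)
    repeats: list = field(default_factory=list)
    gln_tally: gencode.CodonTally | None = None
    motif_counts: dict = field(default_factory=dict)
    at_fraction: float | None = None


@dataclass
class CharacterizationReport:
    per_sequence: list
    aggregates: dict
    failures: list  # (seq_id, message)

    def to_json(self) -> str:
        def clean(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: clean(v) for k, v in asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return json.dumps(clean(self), indent=2, sort_keys=True)

    def profile_frame(self) -> pd.DataFrame:
        """Per-sequence census shaped like the cluster table columns."""
        rows = []
        for rep in self.per_sequence:
            p = rep.profile
            row = {"id": rep.seq_id, "subfamily": rep.subfamily}
            for t in cyspattern.CLUSTER_TYPES:
                row[t] = p.cluster_counts.get(t, 0)
            row.update({"total_cys": p.total_cys, "pct_cys": p.pct_cys,
                        "length": p.length,
                        "capacity": rep.capacity.rounded})
            rows.append(row)
        return pd.DataFrame(rows)


def characterize_one(record: SequenceRecord, config: RunConfig) -> SequenceReport:
    code = gencode.get_code(config.genetic_code)
    tally = None
    motif_counts: dict = {}
    at_fraction = None
    if record.alphabet == "dna":
        orf = record.region("orf")
        if orf is None:
            orf = gencode.find_orf(record, code, min_len=config.min_orf)
        orf_seq = record.subseq(orf)
        protein = gencode.translate(orf_seq, code)
        tally = gencode.tally_gln_codons(orf_seq, code)
        at_fraction = gencode.composition(record).at_fraction
        for kind in ("utr5", "utr3"):
            region = record.region(kind)
            if region is not None:
                defs = utr_motifs.motifs_for_region(kind, config.motifs)
                hits = utr_motifs.scan_motifs(record.subseq(region), defs)
                motif_counts.update(utr_motifs.count_hits(hits))
    else:
        protein = record.residues

    profile = cyspattern.cluster_profile(protein, seq_id=record.id)
    call = cyspattern.classify_subfamily(
        profile, config.threshold_cd, config.threshold_cu, config.cu_max_triple)
    subfamily = config.force_subfamily or call.label

    modularity = None
    modules: list = []
    repeats: list = []
    if subfamily == "CuMT":
        repeats = modules_grammar.find_cump_repeats(protein)
    else:
        modules = modules_grammar.find_module_boundaries(
            protein, config.module_config)
        for m in modules:
            modules_grammar.annotate_submodules(m, protein)
        modularity = modules_grammar.classify_modularity(
            modules, seq_id=record.id, seq_len=len(protein))

    metal = "Cu" if subfamily == "CuMT" else "Cd"
    capacity = metal_capacity.theoretical_capacity(
        profile.total_cys, metal, seq_id=record.id)
    prot_record = SequenceRecord(id=record.id, residues=protein,
                                 alphabet="protein")
    comp = gencode.composition(prot_record)
    return SequenceReport(
        seq_id=record.id, subfamily=subfamily, profile=profile,
        capacity=capacity, composition=comp, protein=protein,
        modularity=modularity, modules=modules, repeats=repeats,
        gln_tally=tally, motif_counts=motif_counts, at_fraction=at_fraction,
    )


def _aggregate(reports: list) -> dict:
    aggregates: dict = {}
    by_sub: dict[str, list] = {}
    for rep in reports:
        by_sub.setdefault(rep.subfamily, []).append(rep)
    for sub, reps in by_sub.items():
        profiles = [r.profile for r in reps]
        census = cyspattern.aggregate_profiles(profiles).loc["all"]
        entry: dict = {"n": len(reps), "cluster_census": census.to_dict()}
        tallies = [r.gln_tally for r in reps if r.gln_tally is not None]
        if tallies:
            totals = {c: sum(t.counts.get(c, 0) for t in tallies)
                      for c in gencode.GLN_CODONS_RNA}
            ratio = gencode.noncanonical_ratio(totals)
            entry["gln_totals"] = totals
            entry["gln_ratio"] = {
                "numerator": ratio.numerator,
                "denominator": ratio.denominator,
                "ratio": None if ratio.ratio is None else round(ratio.ratio, 2),
                "rational": None if ratio.rational is None
                else f"{ratio.numerator}/{ratio.denominator}",
            }
        metal = "Cu" if sub == "CuMT" else "Cd"
        summary = metal_capacity.capacity_summary(profiles, metal)
        entry["capacity_mean_raw"] = round(summary.mean_raw, 2)
        entry["capacity_mean_rounded"] = summary.mean_rounded
        counts = [r.modularity.n_modules for r in reps if r.modularity]
        if counts:
            entry["modularity"] = dict(pd.Series(counts).value_counts())
            entry["modularity"] = {int(k): int(v)
                                   for k, v in entry["modularity"].items()}
        motif_counts = {r.seq_id: r.motif_counts for r in reps
                        if r.motif_counts}
        if motif_counts:
            msum = utr_motifs.motif_summary(motif_counts)
            entry["motif_means"] = msum.group_means.loc["all"].to_dict()
        aggregates[sub] = entry
    return aggregates


def characterize(records: list, config: RunConfig | None = None
                 ) -> CharacterizationReport:
    """Characterize a batch of records; failures are logged, not fatal."""
    config = config or RunConfig()
    if not records:
        raise ValueError("no records to characterize")
    reports = []
    failures = []
    for record in records:
        try:
            reports.append(characterize_one(record, config))
        except (ValueError, KeyError) as exc:
            failures.append((record.id, str(exc)))
    if not reports:
        raise ValueError("no record could be characterized: "
                         + "; ".join(m for _, m in failures))
    return CharacterizationReport(
        per_sequence=reports,
        aggregates=_aggregate(reports),
        failures=failures,
    )
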