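"""Ground-truthed synthetic data emulating a genome-wide gene-family survey.

The generator's defaults reproduce the study conditions of the family it
models: 34 candidate proteins of which 26 are genuine members (8 decoys each
violate exactly one acceptance rule), genes spread over eight of nine
chromosomes with one 2-gene and two 3-gene tandem clusters (intergenic gaps
under 50 kb), sub-genome labels {LF: 14, MF-I: 10, MF-II: 2}, exon layouts
realizing 54 phase-2 introns family-wide, ortholog CDS pairs evolved at known
dN/dS, transcripts with implanted miRNA target sites of known
mismatch/wobble composition, a 26 x 7 FPKM matrix with 19 expressed rows,
and qPCR Ct tables with known fold changes.

All randomness flows from a single integer seed through per-stage
substreams. Every generated dataset is self-validated against its own truth
tables before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evolution, expression, genestruct, mirna, patterns
from .seqio import AMINO_ACIDS, DomainAnnotation, GeneModel, SequenceRecord

_RNA = "ACGU"
_DNA = "ACGT"

#: Synonymous codon choices per amino acid (standard code, no stops).
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in evolution.CODON_TABLE.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition defaults for every generator stage."""

    seed: int
    n_chromosomes: int = 9
    family_size: int = 26
    n_decoys: int = 8
    #: (chromosome, cluster size, max intergenic gap bp) tandem specs
    tandem_cluster_spec: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("C3", 2, 45_000), ("C1", 3, 45_000),
                                 ("C5", 3, 45_000)])
    #: family genes per chromosome (eight of nine carry genes, none on C6)
    chromosome_plan: dict[str, int] = field(
        default_factory=lambda: {"C1": 5, "C2": 2, "C3": 4, "C4": 5,
                                 "C5": 5, "C7": 1, "C8": 2, "C9": 2})
    #: genes involved in segmental duplications (syntenic-block table)
    segmental_gene_count: int = 13
    subgenome_counts: dict[str, int] = field(
        default_factory=lambda: {"LF": 14, "MF-I": 10, "MF-II": 2})
    omega_values: list[float] = field(default_factory=lambda: [0.2, 3.0])
    codon_count: int = 300
    #: implanted site compositions: (mirna idx, gene idx, mismatches, wobbles)
    mirna_site_specs: list[tuple[int, int, int, int]] = field(
        default_factory=lambda: [
            (0, 0, 2, 1),
            (1, 1, 1, 3), (1, 2, 1, 2), (1, 3, 2, 0),
            (1, 4, 1, 1), (1, 4, 2, 1), (1, 5, 1, 2), (1, 5, 2, 2),
            (2, 6, 1, 1), (3, 7, 2, 1), (4, 8, 1, 1)])
    n_expressed: int = 19
    tissues: tuple[str, ...] = ("leaf", "stem", "callus", "root",
                                "silique", "flower", "bud")
    ct_noise_sd: float = 0.1
    qpcr_replicates: int = 3

    def stage_rngs(self, n: int = 8) -> list[np.random.Generator]:
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _motif_instance(pattern: patterns.MotifPattern,
                    rng: np.random.Generator) -> str:
    """One concrete expansion of a compiled pattern."""
    out = []
    for el in pattern.elements:
        count = int(rng.integers(el.min_count, el.max_count + 1))
        pool = sorted(el.residues) if el.residues is not None \
            else list(AMINO_ACIDS)
        out.extend(rng.choice(pool) for _ in range(count))
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
              for aa in protein]
    stop = sorted(evolution.STOP_CODONS)[int(rng.integers(3))]
    return "".join(codons) + stop


def _exon_layout(cds_len: int, phases: list[int], rng: np.random.Generator
                 ) -> list[int]:
    """Exon lengths whose cumulative sums realize the requested intron
    phases (cumulative CDS length mod 3 at each junction)."""
    k = len(phases)
    if k == 0:
        return [cds_len]
    cuts = []
    for i, ph in enumerate(phases, start=1):
        c = round(i * cds_len / (k + 1))
        c += (ph - c) % 3
        cuts.append(c)
    for i in range(1, k):
        if cuts[i] <= cuts[i - 1]:
            raise SimulationError("exon layout infeasible: CDS too short")
    if cuts[-1] >= cds_len:
        raise SimulationError("exon layout infeasible: CDS too short")
    bounds = [0] + cuts + [cds_len]
    return [b - a for a, b in zip(bounds, bounds[1:])]


#: per-gene intron-phase plans summing to 54 phase-2 introns over 26 genes:
#: two 7-exon genes carry three phase-2 introns, four "IV-b-like" genes carry
#: a terminal phase-1 intron, the remainder carry two phase-2 introns.
def _default_phase_plans(family_size: int) -> list[list[int]]:
    plans = []
    for i in range(family_size):
        if i < 2:
            plans.append([0, 2, 0, 2, 0, 2])
        elif i < 6:
            plans.append([0, 2, 2, 0, 1])
        else:
            plans.append([0, 0, 2, 2, 0])
    return plans


@dataclass
class GenomeBundle:
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    models: list[GeneModel]
    annotations: dict[str, DomainAnnotation]
    truth_family: pd.DataFrame        # candidate_id, is_member, violation
    truth_tandem: list[frozenset[str]]
    truth_subgenome: pd.DataFrame     # gene_id, subgenome
    blocks: pd.DataFrame              # gene_a, gene_b (segmental pairs)
    truth_phases: dict[int, int]


def simulate_family_genome(config: SimulationConfig) -> GenomeBundle:
    """Annotated multi-chromosome genome carrying the motif-bearing family.

    Self-validates: classification accepts exactly the family members, the
    tandem caller recovers the planned clusters, and the phase census matches
    the planned totals.
    """
    rng = config.stage_rngs()[0]
    pattern = patterns.compile_pattern(patterns.CNGC_CONSENSUS,
                                       "CNGC_consensus")
    if sum(config.chromosome_plan.values()) != config.family_size:
        raise SimulationError("chromosome plan does not sum to family size")
    for chrom, size, _ in config.tandem_cluster_spec:
        if config.chromosome_plan.get(chrom, 0) < size:
            raise SimulationError(
                f"tandem cluster of {size} exceeds genes on {chrom}")

    phase_plans = _default_phase_plans(config.family_size)
    gene_ids = [f"FamG{i + 1:02d}" for i in range(config.family_size)]

    proteins, cds_records, transcripts, models = [], [], [], []
    annotations: dict[str, DomainAnnotation] = {}

    # --- family members: motif-bearing proteins on planned loci ---
    # assign gene indices to chromosomes in id order
    chrom_of: dict[str, list[str]] = {}
    idx = 0
    for chrom in sorted(config.chromosome_plan):
        count = config.chromosome_plan[chrom]
        chrom_of[chrom] = gene_ids[idx:idx + count]
        idx += count
    # tandem members are the first genes of their chromosome
    tandem_truth: list[frozenset[str]] = []
    tandem_members: set[str] = set()
    for chrom, size, _gap in config.tandem_cluster_spec:
        members = frozenset(chrom_of[chrom][:size])
        tandem_truth.append(members)
        tandem_members |= members

    # small gap applies between consecutive cluster members only: map each
    # member except the last to the cluster's max gap
    gap_for: dict[str, int] = {}
    for chrom, size, max_gap in config.tandem_cluster_spec:
        for g in chrom_of[chrom][:size - 1]:
            gap_for[g] = max_gap

    for i, gid in enumerate(gene_ids):
        length = int(rng.integers(520, 760))
        motif = _motif_instance(pattern, rng)
        pos = int(rng.integers(50, length - len(motif) - 50))
        body = _random_protein(rng, length - len(motif))
        prot = body[:pos] + motif + body[pos:]
        proteins.append(SequenceRecord(gid, prot, "protein"))
        annotations[gid] = DomainAnnotation(
            gid, frozenset({patterns.CNBD_LABEL,
                            patterns.ION_TRANSPORT_LABEL}), "synthetic")
        cds = _reverse_translate(prot, rng)
        cds_records.append(SequenceRecord(gid, cds, "DNA"))
        transcripts.append(SequenceRecord(gid, cds, "DNA"))

    # --- genomic placement ---
    for chrom in sorted(config.chromosome_plan):
        cursor = int(rng.integers(50_000, 150_000))
        for gid in chrom_of[chrom]:
            i = gene_ids.index(gid)
            cds_len = len(cds_records[i].residues)
            exon_lens = _exon_layout(cds_len, phase_plans[i], rng)
            intron_lens = [int(rng.integers(80, 800))
                           for _ in range(len(exon_lens) - 1)]
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor
            exons_plus: list[tuple[int, int]] = []
            p = start
            for j, el in enumerate(exon_lens):
                exons_plus.append((p, p + el - 1))
                p += el
                if j < len(intron_lens):
                    p += intron_lens[j]
            end = p - 1
            # transcription order: ascending on +, descending on -
            if strand == "-":
                # the phase plan is defined in transcription order, so the
                # genomic segment lengths must be reversed for - strand
                lens_rev = exon_lens[::-1]
                exons_plus = []
                p = start
                for j, el in enumerate(lens_rev):
                    exons_plus.append((p, p + el - 1))
                    p += el
                    if j < len(intron_lens):
                        p += intron_lens[j]
                end = p - 1
                exons = exons_plus[::-1]
            else:
                exons = exons_plus
            models.append(GeneModel(gid, chrom, strand, start, end,
                                    exons, family_id="CNGC"))
            if gid in gap_for:
                gap = int(rng.integers(15_000, gap_for[gid]))
            else:
                gap = int(rng.integers(400_000, 1_500_000))
            cursor = end + 1 + gap

    # --- decoys: each violates exactly one acceptance rule ---
    decoy_rows = []
    modes = ["missing_CNBD", "missing_CNBD",
             "missing_ion_transport", "missing_ion_transport",
             "missing_CNGC_motif", "missing_CNGC_motif",
             "truncated", "truncated"][:config.n_decoys]
    for d, mode in enumerate(modes):
        did = f"Decoy{d + 1:02d}"
        length = 150 if mode == "truncated" else int(rng.integers(520, 700))
        if mode == "missing_CNGC_motif":
            while True:  # rejection sampling guarantees motif absence
                prot = _random_protein(rng, length)
                probe = SequenceRecord(did, prot, "protein")
                if not patterns.find_matches(pattern, probe):
                    break
        else:
            motif = _motif_instance(pattern, rng)
            pos = int(rng.integers(10, max(11, length - len(motif) - 10)))
            body = _random_protein(rng, length - len(motif))
            prot = body[:pos] + motif + body[pos:]
        labels = {patterns.CNBD_LABEL, patterns.ION_TRANSPORT_LABEL}
        if mode == "missing_CNBD":
            labels.discard(patterns.CNBD_LABEL)
        elif mode == "missing_ion_transport":
            labels.discard(patterns.ION_TRANSPORT_LABEL)
        proteins.append(SequenceRecord(did, prot, "protein"))
        annotations[did] = DomainAnnotation(did, frozenset(labels),
                                            "synthetic")
        decoy_rows.append({"candidate_id": did, "is_member": False,
                           "violation": mode})

    truth_family = pd.DataFrame(
        [{"candidate_id": g, "is_member": True, "violation": ""}
         for g in gene_ids] + decoy_rows)

    # --- sub-genome assignment and segmental blocks ---
    sub_rows = []
    pos = 0
    for label in ("LF", "MF-I", "MF-II"):
        for g in gene_ids[pos:pos + config.subgenome_counts[label]]:
            sub_rows.append({"gene_id": g, "subgenome": label})
        pos += config.subgenome_counts[label]
    truth_subgenome = pd.DataFrame(sub_rows)

    seg_genes = [g for g in gene_ids if g not in tandem_members]
    seg_genes = seg_genes[:config.segmental_gene_count]
    pairs = [(seg_genes[2 * i], seg_genes[2 * i + 1])
             for i in range(len(seg_genes) // 2)]
    if len(seg_genes) % 2:  # odd count: last gene pairs with the first
        pairs.append((seg_genes[-1], seg_genes[0]))
    blocks = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])

    phase_truth = {0: 0, 1: 0, 2: 0}
    for plan in phase_plans:
        for ph in plan:
            phase_truth[ph] += 1

    bundle = GenomeBundle(proteins, cds_records, transcripts, models,
                          annotations, truth_family, tandem_truth,
                          truth_subgenome, blocks, phase_truth)
    _validate_genome(bundle, pattern)
    return bundle


def _validate_genome(bundle: GenomeBundle,
                     pattern: patterns.MotifPattern) -> None:
    results = patterns.classify_family(bundle.proteins, bundle.annotations,
                                       pattern=pattern)
    accepted = {r.protein_id for r in results if r.verdict == "accepted"}
    members = set(bundle.truth_family.query("is_member")["candidate_id"])
    if accepted != members:
        raise SimulationError(
            f"self-validation failed: classification accepts {accepted} "
            f"!= truth {members}")
    calls = evolution.call_tandem(bundle.models, "CNGC")
    clusters = set(evolution.tandem_clusters(calls))
    if clusters != set(bundle.truth_tandem):
        raise SimulationError("self-validation failed: tandem clusters")
    totals, _ = genestruct.phase_census(bundle.models)
    if totals != bundle.truth_phases:
        raise SimulationError("self-validation failed: intron phases")


# ---------------------------------------------------------------------------
# Codon pairs at known omega
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, codon_count: int) -> str:
    sense = sorted(evolution.CODON_TABLE)
    return "".join(sense[rng.integers(len(sense))]
                   for _ in range(codon_count))


def simulate_codon_pairs(config: SimulationConfig, n_pairs_per_omega: int = 1,
                         proposals_per_site: float = 0.3
                         ) -> pd.DataFrame:
    """CDS pairs evolved at each configured dN/dS.

    Random point mutations are proposed along one copy; synonymous changes
    fix with probability min(1, 1/omega) and nonsynonymous with min(1,
    omega), so the realized dN/dS (relative to neutral) equals omega.
    Proposals creating stop codons are discarded. Returns a DataFrame with
    pair ids, both CDS strings, and the true omega.
    """
    rng = config.stage_rngs()[1]
    rows = []
    n_events = int(round(proposals_per_site * 3 * config.codon_count))
    for omega in config.omega_values:
        p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
        p_non = min(1.0, omega)
        for rep in range(n_pairs_per_omega):
            anc = _random_cds(rng, config.codon_count)
            seq = list(anc)
            for _ in range(n_events):
                site = int(rng.integers(len(seq)))
                base = _DNA[rng.integers(4)]
                if base == seq[site]:
                    continue
                ci = site // 3
                old_codon = "".join(seq[3 * ci:3 * ci + 3])
                new_codon = (old_codon[:site % 3] + base
                             + old_codon[site % 3 + 1:])
                if new_codon in evolution.STOP_CODONS:
                    continue
                syn = (evolution.CODON_TABLE[old_codon]
                       == evolution.CODON_TABLE[new_codon])
                if rng.random() < (p_syn if syn else p_non):
                    seq[site] = base
            rows.append({"pair_id": f"omega{omega}_rep{rep}",
                         "omega": omega, "cds_a": anc,
                         "cds_b": "".join(seq)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# miRNA targets
# ---------------------------------------------------------------------------

_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _implant_site(mirna_3to5: str, n_mismatch: int, n_wobble: int,
                  rng: np.random.Generator) -> str:
    """Target site (5'->3') pairing the miRNA with exactly the requested
    mismatch/wobble composition."""
    site = [_WC_PARTNER[b] for b in mirna_3to5]
    wobble_ok = [i for i, b in enumerate(mirna_3to5) if b in "GU"]
    if n_wobble > len(wobble_ok):
        raise SimulationError("not enough G/U positions for wobbles")
    chosen_w = list(rng.choice(wobble_ok, size=n_wobble, replace=False))
    remaining = [i for i in range(len(site)) if i not in chosen_w]
    chosen_m = list(rng.choice(remaining, size=n_mismatch, replace=False))
    for i in chosen_w:
        site[i] = "U" if mirna_3to5[i] == "G" else "G"
    for i in chosen_m:
        bad = [b for b in _RNA
               if mirna.pair_state(mirna_3to5[i], b) == "mismatch"]
        site[i] = bad[rng.integers(len(bad))]
    return "".join(site)


@dataclass
class MirnaBundle:
    mirnas: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    truth_sites: pd.DataFrame  # mirna_id, gene_id, position, expectation


def simulate_mirna_targets(config: SimulationConfig,
                           transcript_length: int = 400,
                           cutoff: float = mirna.CUTOFF_STRINGENT,
                           max_retries: int = 50) -> MirnaBundle:
    """miRNAs + transcripts with implanted sites of known penalty
    composition; background windows verified to exceed the cutoff."""
    rng = config.stage_rngs()[2]
    n_mirnas = max(s[0] for s in config.mirna_site_specs) + 1
    n_genes = max(s[1] for s in config.mirna_site_specs) + 1
    mirnas = []
    for i in range(n_mirnas):
        length = int(rng.integers(20, 23))
        seq = "".join(rng.choice(list(_RNA), size=length))
        mirnas.append(SequenceRecord(f"syn-miR{i + 1}", seq, "RNA"))

    by_gene: dict[int, list[tuple[int, int, int]]] = {}
    for mi, gi, nm, nw in config.mirna_site_specs:
        by_gene.setdefault(gi, []).append((mi, nm, nw))

    transcripts = []
    truth_rows = []
    for gi in range(n_genes):
        gid = f"SynT{gi + 1:02d}"
        specs = by_gene.get(gi, [])
        for _attempt in range(max_retries):
            background = "".join(rng.choice(list(_RNA),
                                            size=transcript_length))
            seq = background
            placed = []
            pos_cursor = 30
            ok = True
            for mi, nm, nw in specs:
                m = mirnas[mi]
                m3to5 = m.residues[::-1]
                site = _implant_site(m3to5, nm, nw, rng)
                start = pos_cursor + int(rng.integers(0, 20))
                if start + len(site) > len(seq) - 30:
                    ok = False
                    break
                seq = seq[:start] + site + seq[start + len(site):]
                placed.append((m, start + 1, nm + 0.5 * nw))
                pos_cursor = start + len(site) + 25
            if not ok:
                continue
            transcript = SequenceRecord(gid, seq, "RNA")
            # verify: every miRNA finds exactly its implanted sites
            found_ok = True
            for m in mirnas:
                rep = mirna.scan_transcript(m, transcript, cutoff)
                expect = {(p, e) for mm, p, e in placed if mm.id == m.id}
                got = {(s.target_start, s.expectation) for s in rep.sites}
                if got != expect:
                    found_ok = False
                    break
            if found_ok:
                transcripts.append(transcript)
                for m, p, e in placed:
                    truth_rows.append({"mirna_id": m.id, "gene_id": gid,
                                       "position": p, "expectation": e})
                break
        else:
            raise SimulationError(
                f"could not build a clean transcript for gene {gid}")
    truth = pd.DataFrame(truth_rows)
    return MirnaBundle(mirnas, transcripts, truth)


# ---------------------------------------------------------------------------
# Expression and qPCR
# ---------------------------------------------------------------------------

@dataclass
class ExpressionBundle:
    fpkm: pd.DataFrame
    truth_expressed: pd.Series
    ct_table: pd.DataFrame
    truth_log2_fold: pd.Series


def simulate_expression(config: SimulationConfig,
                        gene_ids: list[str] | None = None,
                        log2_folds: dict[str, float] | None = None
                        ) -> ExpressionBundle:
    """FPKM matrix with a known expressed set and Ct tables with known
    fold changes.

    Expressed rows draw from a long-tailed lognormal (guaranteed above the
    FPKM>1 call threshold in at least one tissue); silent rows stay below it
    everywhere. Ct values follow the Livak model: the treated-vs-control
    difference of (Ct_target - Ct_reference) equals -log2 fold plus Gaussian
    noise.
    """
    rng = config.stage_rngs()[3]
    if gene_ids is None:
        gene_ids = [f"FamG{i + 1:02d}" for i in range(config.family_size)]
    n = len(gene_ids)
    if config.n_expressed > n:
        raise SimulationError("more expressed rows than genes")
    expressed_idx = set(rng.choice(n, size=config.n_expressed, replace=False))
    rows = []
    for i in range(n):
        if i in expressed_idx:
            vals = rng.lognormal(mean=1.2, sigma=1.2, size=len(config.tissues))
            if vals.max() <= 1.0:
                vals[rng.integers(len(vals))] = 1.0 + rng.lognormal(0.5, 0.5)
        else:
            vals = rng.uniform(0.0, 0.9, size=len(config.tissues))
        rows.append(vals)
    fpkm = pd.DataFrame(rows, index=gene_ids, columns=list(config.tissues))
    truth_expressed = pd.Series(
        [i in expressed_idx for i in range(n)], index=gene_ids)

    if log2_folds is None:
        fold_choices = [0.0, 1.0, 2.0, -1.0]
        log2_folds = {g: float(fold_choices[rng.integers(len(fold_choices))])
                      for g in gene_ids}
    ct_rows = []
    for g in gene_ids:
        base = float(rng.uniform(22, 28))
        for cond in ("control", "treated"):
            shift = -log2_folds[g] if cond == "treated" else 0.0
            for rep in range(1, config.qpcr_replicates + 1):
                ct_rows.append({
                    "gene": g, "condition": cond, "replicate": rep,
                    "ct_target": base + shift
                    + float(rng.normal(0, config.ct_noise_sd)),
                    "ct_reference": 20.0
                    + float(rng.normal(0, config.ct_noise_sd)),
                })
    ct_table = pd.DataFrame(ct_rows)
    truth_fold = pd.Series(log2_folds)

    # self-validation: the expressed-call truth must hold by construction
    calls, _ = expression.expressed_calls(fpkm, 1.0)
    if not (calls == truth_expressed).all():
        raise SimulationError("self-validation failed: expressed calls")
    return ExpressionBundle(fpkm, truth_expressed, ct_table, truth_fold)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_genome_bundle(bundle: GenomeBundle, outdir) -> dict[str, str]:
    """Write a genome bundle as FASTA/GFF3/TSV plus truth tables; returns a
    name -> path map."""
    import os

    from . import seqio

    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
    paths = {
        "proteins": os.path.join(outdir, "proteins.faa"),
        "cds": os.path.join(outdir, "cds.fna"),
        "transcripts": os.path.join(outdir, "transcripts.fna"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "domains": os.path.join(outdir, "domains.tsv"),
        "subgenome": os.path.join(outdir, "subgenome.tsv"),
        "blocks": os.path.join(outdir, "blocks.tsv"),
        "truth_family": os.path.join(outdir, "truth", "family.tsv"),
        "truth_tandem": os.path.join(outdir, "truth", "tandem.tsv"),
        "truth_phases": os.path.join(outdir, "truth", "phases.tsv"),
    }
    seqio.write_fasta(bundle.proteins, paths["proteins"])
    seqio.write_fasta(bundle.cds, paths["cds"])
    seqio.write_fasta(bundle.transcripts, paths["transcripts"])
    seqio.write_gff3(bundle.models, paths["gff3"])
    dom = pd.DataFrame(
        [{"protein_id": a.protein_id,
          "domain_labels": ",".join(sorted(a.domain_labels)),
          "source": a.source} for a in bundle.annotations.values()])
    seqio.write_tsv_report(dom, paths["domains"])
    seqio.write_tsv_report(bundle.truth_subgenome, paths["subgenome"])
    seqio.write_tsv_report(bundle.blocks, paths["blocks"])
    seqio.write_tsv_report(bundle.truth_family, paths["truth_family"])
    seqio.write_tsv_report(
        pd.DataFrame([{"cluster": i + 1, "genes": ",".join(sorted(c))}
                      for i, c in enumerate(bundle.truth_tandem)]),
        paths["truth_tandem"])
    seqio.write_tsv_report(
        pd.DataFrame([{"phase": k, "count": v}
                      for k, v in sorted(bundle.truth_phases.items())]),
        paths["truth_phases"])
    return paths
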