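"""Synthetic multi-tissue transcriptomes with planted ground truth.

The generator emulates the input of a multi-tissue lncRNA discovery run:
five truth classes of transcript, each designed to be removed by exactly
one filter (or none), on a virtual chromosome namespace (chrS1..chrSn plus
an unplaced chrUn scaffold):

* ``coding`` — carries an ATG-initiated ORF of >= 100 aa reverse-translated
  from a bundled protein fixture database, so the coding-potential filter
  removes it;
* ``true_lncRNA`` — random sequence >= 200 bp, expressed, placed away from
  genes; survives every filter. A configurable fraction additionally
  carries a protein-matching ORF *and* a near-identical entry in the
  lncRNA fixture database: these are removed by the coding filter and then
  rescued, emulating conserved lncRNA lost to protein-level evidence;
* ``utr_fragment`` — placed within 1 kb of a planted protein-coding gene
  span on the same strand (the fragmented-UTR failure mode), removed by
  the proximity filter;
* ``short`` — spliced length < 200 bp, removed by the length filter;
* ``low_expression`` — mean TPM < 0.1 in every tissue, removed by the
  expression filter.

Tissues follow the mixed library-prep structure of multi-tissue equine
RNA-seq (three rRNA-depleted CNS tissues, three polyA-captured, two
Ovation-prepped embryonic tissues). Non-polyadenylated transcripts have
their TPM attenuated in polyA-captured (and, less strongly, Ovation)
tissues, reproducing the under-detection of lncRNA in polyA libraries.

All randomness flows through one seeded ``numpy`` generator; a given
config is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coding_potential import _CODON_TABLE
from .genomic_filters import GeneSpan
from .io_model import Category, ExpressionMatrix, TranscriptRecord, write_results

__all__ = ["SimConfig", "SimulatedDataset", "generate", "perturb",
           "conservation_contrast"]

_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TABLE.items()):
    if aa != "*":
        _AA_CODONS.setdefault(aa, []).append(codon)
_AMINO_ACIDS = sorted(_AA_CODONS)
_STOPS = ("TAA", "TAG", "TGA")

DEFAULT_TISSUES: tuple[tuple[str, str], ...] = (
    ("spinal_cord", "rRNA_depleted"),
    ("brainstem", "rRNA_depleted"),
    ("cerebellum", "rRNA_depleted"),
    ("muscle", "polyA"),
    ("retina", "polyA"),
    ("skin", "polyA"),
    ("embryo_ICM", "ovation"),
    ("embryo_TE", "ovation"),
)

# class -> (input-category choices, probabilities): coding-like material
# concentrates in novel I, true lncRNA in the intergenic/known groups
_CATEGORY_MODEL: dict[str, tuple[list[Category], list[float]]] = {
    "coding": ([Category.novel_I, Category.novel_II, Category.novel_III],
               [0.7, 0.2, 0.1]),
    "true_lncRNA": ([Category.intergenic, Category.known_lncRNA, Category.novel_II],
                    [0.7, 0.2, 0.1]),
    "utr_fragment": ([Category.novel_I, Category.novel_III, Category.intergenic],
                     [0.5, 0.3, 0.2]),
    "short": ([Category.intergenic], [1.0]),
    "low_expression": ([Category.intergenic, Category.novel_III], [0.7, 0.3]),
}

_FATE = {"coding": "F3", "true_lncRNA": "none", "utr_fragment": "F4",
         "short": "F2", "low_expression": "F1"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic transcriptome."""

    seed: int = 42
    n_coding: int = 400
    n_true_lncrna: int = 800
    n_utr_fragment: int = 300
    n_short: int = 250
    n_low_expression: int = 250
    tissues: tuple[tuple[str, str], ...] = DEFAULT_TISSUES
    # planted homology
    rescue_fraction: float = 0.05  # of true lncRNA: coding-ORF + lnc-db match
    rescue_db_mutation_rate: float = 0.05
    orf_mutation_rate: float = 0.0
    # expression model
    tissue_specific_fraction: float = 0.15  # of true lncRNA: one-tissue expression
    nonpolya_fraction: float = 0.5  # of non-coding transcripts lacking a polyA tail
    polya_attenuation: float = 0.25  # TPM multiplier in polyA tissues
    ovation_attenuation: float = 0.5
    # fixtures and genome layout
    n_proteins: int = 50
    protein_len_range: tuple[int, int] = (110, 300)
    n_motifs: int = 10
    n_decoy_lnc: int = 20
    n_chroms: int = 4
    n_genes_per_chrom: int = 30
    gc_content: float = 0.45
    short_len_range: tuple[int, int] = (60, 199)
    lnc_len_range: tuple[int, int] = (250, 4000)

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_true_lncrna", "n_utr_fragment", "n_short",
                     "n_low_expression"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_short > 0 and self.short_len_range[0] >= 200:
            raise ValueError("short class requested but minimum length >= 200 bp")
        if self.short_len_range[1] >= 200:
            raise ValueError("short_len_range upper bound must stay below 200 bp")
        if not 0 <= self.rescue_fraction <= 1:
            raise ValueError("rescue_fraction must be in [0, 1]")
        if self.n_utr_fragment > 0 and self.n_chroms * self.n_genes_per_chrom == 0:
            raise ValueError("utr fragments requested but no genes planted")

    @property
    def n_per_class(self) -> dict[str, int]:
        return {
            "coding": self.n_coding,
            "true_lncRNA": self.n_true_lncrna,
            "utr_fragment": self.n_utr_fragment,
            "short": self.n_short,
            "low_expression": self.n_low_expression,
        }


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus the truth table."""

    records: list[TranscriptRecord]
    expr: ExpressionMatrix
    genes: list[GeneSpan]
    protein_db: dict[str, str]
    lnc_db: dict[str, str]
    motifs: list[tuple[str, str]]
    truth: pd.DataFrame  # index transcript_id; class, expected_fate, expected_rescue, planted_tissue
    config: SimConfig

    def write(self, outdir: Path | str) -> dict[str, Path]:
        """Emit all inputs as plain-text files; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / fn for name, fn in [
            ("transcripts_gtf", "transcripts.gtf"), ("transcripts_fasta", "transcripts.fa"),
            ("expression", "expression.tsv"), ("tissues", "tissues.tsv"),
            ("genes_gtf", "genes.gtf"), ("proteins", "proteins.faa"),
            ("lnc_db", "lncdb.fa"), ("motifs", "motifs.txt"),
            ("truth", "truth.tsv"), ("manifest", "sim_manifest.json"),
        ]}
        write_results(self.records, gtf_path=paths["transcripts_gtf"],
                      fasta_path=paths["transcripts_fasta"])
        self.expr.values.round(6).to_csv(paths["expression"], sep="\t",
                                         index_label="transcript_id")
        with open(paths["tissues"], "w") as fh:
            fh.write("tissue\tlibrary_prep\n")
            for name, prep in self.config.tissues:
                fh.write(f"{name}\t{prep}\n")
        with open(paths["genes_gtf"], "w") as fh:
            for g in self.genes:
                attrs = (f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                         f'category "protein_coding";')
                fh.write("\t".join([g.chrom, "equilnc", "exon", str(g.start),
                                    str(g.end), ".", g.strand, ".", attrs]) + "\n")
        for key, db in (("proteins", self.protein_db), ("lnc_db", self.lnc_db)):
            with open(paths[key], "w") as fh:
                for sid in db:
                    fh.write(f">{sid}\n{db[sid]}\n")
        with open(paths["motifs"], "w") as fh:
            for name, pat in self.motifs:
                fh.write(f"{name}\t{pat}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index_label="transcript_id")
        with open(paths["manifest"], "w") as fh:
            json.dump({"seed": self.config.seed, "config": asdict(self.config)},
                      fh, indent=1, default=list)
            fh.write("\n")
        return paths


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = np.array(list("ACGT"))
    for i in hits:
        arr[i] = rng.choice(bases[bases != arr[i]])
    return "".join(arr)


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(rng.choice(_AA_CODONS[aa]) for aa in peptide) + str(rng.choice(_STOPS))


def _exon_layout(rng: np.random.Generator, spliced_len: int, n_exons: int,
                 start: int) -> tuple[tuple[int, int], ...]:
    n_exons = max(1, min(n_exons, spliced_len // 30))
    base = 30
    extra = rng.multinomial(spliced_len - base * n_exons, np.full(n_exons, 1 / n_exons))
    sizes = base + extra
    introns = rng.integers(100, 1500, size=n_exons - 1) if n_exons > 1 else []
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + int(size) - 1))
        pos += int(size) + (int(introns[i]) if i < n_exons - 1 else 0)
    return tuple(exons)


def generate(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Generate one synthetic transcriptome dataset from a config."""
    rng = np.random.default_rng(config.seed)

    # fixture protein database and motif patterns
    protein_db: dict[str, str] = {}
    for i in range(config.n_proteins):
        plen = int(rng.integers(*config.protein_len_range))
        protein_db[f"P{i + 1:04d}"] = "M" + "".join(
            rng.choice(_AMINO_ACIDS, size=plen - 1))
    motifs: list[tuple[str, str]] = []
    for i in range(config.n_motifs):
        aas = rng.choice(_AMINO_ACIDS, size=10)
        pat = (f"{aas[0]}-{aas[1]}-x(2)-{aas[2]}-[{aas[3]}{aas[4]}]-"
               f"{aas[5]}-{aas[6]}-{aas[7]}-{aas[8]}")
        motifs.append((f"MOTIF_{i + 1:02d}", pat))

    # virtual genome: genes every 60 kb on chrS*; chrUn has no genes
    chroms = [f"chrS{i + 1}" for i in range(config.n_chroms)] + ["chrUn_0001"]
    genes: list[GeneSpan] = []
    for ci in range(config.n_chroms):
        for g in range(config.n_genes_per_chrom):
            start = g * 60_000 + 10_000
            glen = int(rng.integers(3000, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneSpan(gene_id=f"GENE_{chroms[ci]}_{g + 1:03d}",
                                  chrom=chroms[ci], strand=strand,
                                  start=start, end=start + glen))
    genes_by_chrom: dict[str, list[GeneSpan]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    def far_placement(extent: int) -> tuple[str, int, str]:
        chrom = chroms[int(rng.integers(len(chroms)))]
        slot = int(rng.integers(max(1, config.n_genes_per_chrom)))
        start = slot * 60_000 + 30_000 + int(rng.integers(0, 15_000))
        strand = "+" if rng.random() < 0.5 else "-"
        return chrom, start, strand

    protein_ids = sorted(protein_db)
    tissue_names = [t for t, _ in config.tissues]
    n_tissues = len(tissue_names)

    records: list[TranscriptRecord] = []
    truth_rows: list[dict] = []
    tpm_rows: list[np.ndarray] = []
    rescue_sources: list[tuple[str, str]] = []  # (transcript_id, sequence)

    n_rescue = int(round(config.rescue_fraction * config.n_true_lncrna))
    n_specific = int(round(config.tissue_specific_fraction * config.n_true_lncrna))

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"T{counter:06d}"

    # coding transcripts and rescue lncRNA draw ORFs from disjoint protein
    # pools: two reverse-translations of one protein are ~75% identical at
    # the nucleotide level (shared codon prefixes), close enough to the
    # rescue identity cutoff to cross-contaminate the rescue database
    n_rescue_pool = max(1, len(protein_ids) // 5)
    pools = {"coding": protein_ids[:-n_rescue_pool] or protein_ids,
             "rescue": protein_ids[-n_rescue_pool:]}

    def plant_orf_sequence(pool: str = "coding") -> str:
        ids = pools[pool]
        pid = ids[int(rng.integers(len(ids)))]
        orf_nt = _reverse_translate(rng, protein_db[pid])
        orf_nt = _mutate(rng, orf_nt, config.orf_mutation_rate)
        f5 = _random_seq(rng, int(rng.integers(30, 400)), config.gc_content)
        f3 = _random_seq(rng, int(rng.integers(30, 400)), config.gc_content)
        return f5 + orf_nt + f3

    def lnc_length() -> int:
        lo, hi = config.lnc_len_range
        return int(np.clip(rng.lognormal(np.log(800), 0.6), lo, hi))

    def base_expression(median: float, sigma: float = 0.8) -> np.ndarray:
        base = rng.lognormal(np.log(median), sigma)
        return base * rng.lognormal(0.0, 0.5, size=n_tissues)

    def attenuate(tpm: np.ndarray, polyadenylated: bool) -> np.ndarray:
        if polyadenylated:
            return tpm
        out = tpm.copy()
        for j, (_, prep) in enumerate(config.tissues):
            if prep == "polyA":
                out[j] *= config.polya_attenuation
            elif prep == "ovation":
                out[j] *= config.ovation_attenuation
        return out

    def enforce_detectable(tpm: np.ndarray, single_exon: bool) -> np.ndarray:
        # the generator guarantees expressed classes pass the expression filter
        out = tpm.copy()
        mean = out.mean()
        if mean < 0.18:
            out *= 0.18 / max(mean, 1e-12)
        if single_exon and out.max() < 5.5:
            out *= 5.5 / out.max()
        return out

    def add_transcript(cls: str, seq: str, chrom: str, start: int, strand: str,
                       n_exons: int, tpm: np.ndarray,
                       planted_tissue: str | None = None,
                       expected_rescue: bool = False,
                       exons: tuple[tuple[int, int], ...] | None = None
                       ) -> TranscriptRecord:
        tid = next_id()
        cats, probs = _CATEGORY_MODEL[cls]
        cat = cats[int(rng.choice(len(cats), p=probs))]
        if exons is None:
            exons = _exon_layout(rng, len(seq), n_exons, start)
        rec = TranscriptRecord(transcript_id=tid, gene_id=tid, category=cat,
                               chrom=chrom, strand=strand, exons=exons,
                               sequence=seq)
        records.append(rec)
        fate = "none" if expected_rescue else _FATE[cls]
        truth_rows.append({"transcript_id": tid, "class": cls,
                           "expected_fate": fate,
                           "expected_rescue": expected_rescue,
                           "planted_tissue": planted_tissue or ""})
        tpm_rows.append(tpm)
        return rec

    # --- coding class: planted protein-matching ORFs, removed by Filter 3
    for _ in range(config.n_coding):
        seq = plant_orf_sequence()
        chrom, start, strand = far_placement(len(seq))
        n_exons = int(rng.integers(1, 7))
        tpm = attenuate(base_expression(10.0), True)
        tpm = enforce_detectable(tpm, n_exons == 1)
        add_transcript("coding", seq, chrom, start, strand, n_exons, tpm)

    # --- true lncRNA: rescue subset, tissue-specific subset, background
    for i in range(config.n_true_lncrna):
        is_rescue = i < n_rescue
        is_specific = (not is_rescue) and i < n_rescue + n_specific
        if is_rescue:
            seq = plant_orf_sequence("rescue")
        else:
            seq = _random_seq(rng, lnc_length(), config.gc_content)
        chrom, start, strand = far_placement(len(seq))
        n_exons = int(rng.integers(1, 5))
        polyadenylated = rng.random() >= config.nonpolya_fraction
        planted = None
        if is_specific:
            planted = tissue_names[int(rng.integers(n_tissues))]
            tpm = np.zeros(n_tissues)
            tpm[tissue_names.index(planted)] = max(rng.lognormal(np.log(20), 0.7), 1.0)
        else:
            tpm = base_expression(1.0)
        tpm = attenuate(tpm, polyadenylated)
        tpm = enforce_detectable(tpm, n_exons == 1)
        if not is_specific:
            # background lncRNA must never mimic planted tissue specificity:
            # guarantee detectable expression in at least two tissues
            second = np.sort(tpm)[-2]
            if second < 0.15:
                tpm = tpm * (0.15 / second)
        rec = add_transcript("true_lncRNA", seq, chrom, start, strand, n_exons,
                             tpm, planted_tissue=planted, expected_rescue=is_rescue)
        if is_rescue:
            rescue_sources.append((rec.transcript_id, seq))

    # --- UTR fragments: within 1 kb of a gene, same strand, removed by Filter 4
    for _ in range(config.n_utr_fragment):
        seq = _random_seq(rng, int(np.clip(rng.lognormal(np.log(500), 0.4), 200, 1200)),
                          config.gc_content)
        gene = genes[int(rng.integers(len(genes)))]
        d = int(rng.integers(1, 1001))
        n_exons = int(rng.integers(1, 4))
        # lay the exons out first so the genomic extent is exact, then shift
        # the fragment to start (3' side) or end (5' side) within d of the gene
        layout = _exon_layout(rng, len(seq), n_exons, 1)
        extent = layout[-1][1] - layout[0][0] + 1
        if rng.random() < 0.5:
            start = gene.end + d
        else:
            start = max(1, gene.start - d - extent + 1)
        exons = tuple((a + start - 1, b + start - 1) for a, b in layout)
        tpm = attenuate(base_expression(5.0), rng.random() >= config.nonpolya_fraction)
        tpm = enforce_detectable(tpm, n_exons == 1)
        add_transcript("utr_fragment", seq, gene.chrom, start, gene.strand,
                       n_exons, tpm, exons=exons)

    # --- short transcripts: < 200 bp, removed by Filter 2
    for _ in range(config.n_short):
        length = int(rng.integers(config.short_len_range[0],
                                  config.short_len_range[1] + 1))
        seq = _random_seq(rng, length, config.gc_content)
        chrom, start, strand = far_placement(length)
        n_exons = int(rng.integers(1, 3))
        tpm = attenuate(base_expression(5.0), True)
        tpm = enforce_detectable(tpm, n_exons == 1)
        add_transcript("short", seq, chrom, start, strand, n_exons, tpm)

    # --- low-expression noise: mean TPM < 0.1 everywhere, removed by Filter 1
    for _ in range(config.n_low_expression):
        seq = _random_seq(rng, int(np.clip(rng.lognormal(np.log(800), 0.5), 250, 2000)),
                          config.gc_content)
        chrom, start, strand = far_placement(len(seq))
        tpm = rng.uniform(0.0, 0.09, size=n_tissues)
        add_transcript("low_expression", seq, chrom, start, strand,
                       int(rng.integers(2, 5)), tpm)

    # UTR fragments on the 5' side may have been placed by an extent guess;
    # verify the planted proximity invariant rather than trust it
    from .genomic_filters import apply_filter4

    utr_recs = [r for r, t in zip(records, truth_rows) if t["class"] == "utr_fragment"]
    _, removed = apply_filter4(utr_recs, genes)
    if len(removed) != len(utr_recs):
        missed = {r.transcript_id for r in utr_recs} - {r.transcript_id for r in removed}
        raise RuntimeError(f"generator bug: utr fragments not within 1 kb: {missed}")

    # lncRNA fixture database: mutated copies of the rescue transcripts + decoys
    lnc_db: dict[str, str] = {}
    for i, (_tid, seq) in enumerate(rescue_sources):
        lnc_db[f"HLNC{i + 1:04d}"] = _mutate(rng, seq, config.rescue_db_mutation_rate)
    for i in range(config.n_decoy_lnc):
        lnc_db[f"HDEC{i + 1:04d}"] = _random_seq(
            rng, int(rng.integers(400, 1500)), config.gc_content)

    expr = ExpressionMatrix(
        pd.DataFrame(np.array(tpm_rows) if tpm_rows else np.empty((0, n_tissues)),
                     index=pd.Index([t["transcript_id"] for t in truth_rows],
                                    name="transcript_id"),
                     columns=tissue_names),
        dict(config.tissues),
    )
    truth = pd.DataFrame(truth_rows).set_index("transcript_id") if truth_rows else \
        pd.DataFrame(columns=["class", "expected_fate", "expected_rescue",
                              "planted_tissue"])
    return SimulatedDataset(records=records, expr=expr, genes=genes,
                            protein_db=protein_db, lnc_db=lnc_db, motifs=motifs,
                            truth=truth, config=config)


def conservation_contrast(
    seed: int,
    n_queries: int = 40,
    n_db: int = 30,
    seq_len: int = 600,
    coding_mutation: float = 0.05,
    lnc_conserved_fraction: float = 0.1,
    lnc_mutation: float = 0.35,
    gc: float = 0.45,
):
    """Paired conservation curves for a planted lncRNA-vs-coding contrast.

    Builds a reference transcript database of ``n_db`` random sequences;
    "coding" queries are lightly mutated copies of database entries while
    "lncRNA" queries are random sequence (a small fraction are heavily
    mutated copies, emulating the rare conserved lncRNA). Returns
    ``(lnc_curve, coding_curve)`` — the lncRNA CDF is expected to lie on or
    above the coding CDF at every conservation score.
    """
    from .homology import conservation_curve

    rng = np.random.default_rng(seed)
    db = {f"REF{i + 1:04d}": _random_seq(rng, seq_len, gc) for i in range(n_db)}
    db_ids = sorted(db)

    def rec(tid: str, seq: str) -> TranscriptRecord:
        return TranscriptRecord(transcript_id=tid, chrom="chrS1", strand="+",
                                exons=((1, len(seq)),), sequence=seq)

    coding = [rec(f"C{i:04d}", _mutate(rng, db[db_ids[int(rng.integers(n_db))]],
                                       coding_mutation))
              for i in range(n_queries)]
    n_conserved = int(round(lnc_conserved_fraction * n_queries))
    lnc = [rec(f"L{i:04d}",
               _mutate(rng, db[db_ids[int(rng.integers(n_db))]], lnc_mutation)
               if i < n_conserved else _random_seq(rng, seq_len, gc))
           for i in range(n_queries)]
    return conservation_curve(lnc, db), conservation_curve(coding, db)


def perturb(
    dataset: SimulatedDataset,
    mutation_rate: float = 0.0,
    expression_jitter_sd: float = 0.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Degrade a dataset: point mutations and multiplicative TPM jitter.

    At zero noise the dataset is returned with identical content. Truth
    labels are carried over unchanged — degraded data is for robustness
    curves, where recovery is *expected* to decay.
    """
    if mutation_rate < 0 or expression_jitter_sd < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng(seed)
    new_records = [
        r if mutation_rate == 0 or r.sequence is None
        else r.with_sequence(_mutate(rng, r.sequence, mutation_rate))
        for r in dataset.records
    ]
    vals = dataset.expr.values
    if expression_jitter_sd > 0:
        vals = vals * np.exp(rng.normal(0.0, expression_jitter_sd, size=vals.shape))
    new_expr = ExpressionMatrix(vals.copy(), dict(dataset.expr.library_prep))
    return replace(dataset, records=new_records, expr=new_expr)
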