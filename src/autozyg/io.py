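"""Readers and writers for the pipeline's standard file formats.

Fixture bundles are written as plain-text standards: FASTA (reference),
GFF3 (transcript models, 1-based inclusive), VCF v4.2 (cohort and panel
calls), PLINK text PED/MAP (array genotypes), BED (truth intervals, 0-based
half-open), TSV (sample sheet, ROH and funnel tables) and JSON (ground
truth, manifest). Reading goes through established parsers (pyfaidx for
FASTA, gffutils for GFF3, cyvcf2 for VCF); PED/MAP text is parsed here as
no installed library reads that dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from cyvcf2 import VCF
from pyfaidx import Fasta

from .consequence import TranscriptModel, VariantRecord
from .filtering import CohortGenotypes, FilterFunnel
from .roh import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, ROHSegment, SharedRegion
from .segregation import SampleInfo, SampleSheet
from .simulate import SimBundle, SimTruth

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_transcripts",
    "write_vcf",
    "read_vcf",
    "write_ped_map",
    "read_ped_map",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_truth",
    "read_truth",
    "write_roh_tsv",
    "write_regions",
    "write_funnel",
    "write_fixture",
]

_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_fasta(contigs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    fa = Fasta(str(path))
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def _cds_phases(tx: TranscriptModel) -> list[int]:
    """GFF3 phase per exon, in genomic order."""
    order = range(len(tx.exons)) if tx.strand == "+" else range(len(tx.exons) - 1, -1, -1)
    phases = [0] * len(tx.exons)
    cum = 0
    for i in order:
        phases[i] = (3 - cum % 3) % 3
        cum += tx.exons[i][1] - tx.exons[i][0] + 1
    return phases


def write_gff3(transcripts: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            gene = tx.gene or tx.id
            lo, hi = tx.exons[0][0], tx.exons[-1][1]
            fh.write(
                f"{tx.chrom}\tautozyg\tgene\t{lo}\t{hi}\t.\t{tx.strand}\t.\tID={gene}\n"
            )
            fh.write(
                f"{tx.chrom}\tautozyg\tmRNA\t{lo}\t{hi}\t.\t{tx.strand}\t.\t"
                f"ID={tx.id};Parent={gene}\n"
            )
            phases = _cds_phases(tx)
            for k, (s, e) in enumerate(tx.exons):
                fh.write(
                    f"{tx.chrom}\tautozyg\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.id}.exon{k+1};Parent={tx.id}\n"
                )
                fh.write(
                    f"{tx.chrom}\tautozyg\tCDS\t{s}\t{e}\t.\t{tx.strand}\t{phases[k]}\t"
                    f"ID={tx.id}.cds{k+1};Parent={tx.id}\n"
                )


def read_transcripts(gff_path: str | Path, fasta_path: str | Path) -> list[TranscriptModel]:
    """Rebuild transcript models from GFF3 + FASTA via gffutils."""
    import gffutils
    from Bio.Seq import Seq

    db = gffutils.create_db(str(gff_path), ":memory:", force=True, keep_order=True)
    fa = Fasta(str(fasta_path))
    out: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        exons = tuple((f.start, f.end) for f in cds)
        pieces = [str(fa[mrna.seqid][f.start - 1 : f.end]) for f in cds]
        spliced = "".join(pieces)
        if mrna.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        parents = list(db.parents(mrna, featuretype="gene"))
        out.append(
            TranscriptModel(
                id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_sequence=spliced,
                gene=parents[0].id if parents else "",
            )
        )
    fa.close()
    out.sort(key=lambda t: int(t.id.replace("tx", "")) if t.id.startswith("tx") else 0)
    return out


def write_vcf(
    cohort: CohortGenotypes,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    samples: list[str] | None = None,
) -> int:
    """Write genotype calls as uncompressed VCF v4.2; returns record count."""
    keep = samples if samples is not None else cohort.samples
    cols = [cohort.samples.index(s) for s in keep]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(keep) + "\n")
        for i, v in enumerate(cohort.variants):
            gts = "\t".join(_GT_STRING[int(cohort.calls[i, j])] for j in cols)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.key}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return len(cohort.variants)


def read_vcf(path: str | Path, roles: dict[str, str] | None = None) -> CohortGenotypes:
    """Read a VCF into a CohortGenotypes; unknown samples default to 'control'."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    remap = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)
    for rec in vcf:
        variants.append(
            VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rec.ID or "")
        )
        rows.append(remap[rec.gt_types])
    vcf.close()
    calls = np.stack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    role_map = {s: (roles or {}).get(s, "control") for s in samples}
    return CohortGenotypes(variants, samples, role_map, calls)


def write_ped_map(
    matrix: GenotypeMatrix, prefix: str | Path, phenotypes: dict[str, int] | None = None
) -> tuple[Path, Path]:
    """PLINK text dialect: <prefix>.ped and <prefix>.map."""
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for c, p, mid in zip(matrix.chroms, matrix.positions, matrix.marker_ids):
            fh.write(f"{c}\t{mid}\t0\t{p}\n")
    allele_pairs = {
        HOM_REF: ("A", "A"),
        HET: ("A", "B"),
        HOM_ALT: ("B", "B"),
        MISSING: ("0", "0"),
    }
    with open(ped_path, "w") as fh:
        for j, sample in enumerate(matrix.samples):
            pheno = (phenotypes or {}).get(sample, 0)
            fields = [sample, sample, "0", "0", "0", str(pheno)]
            for i in range(matrix.n_markers):
                a, b = allele_pairs[int(matrix.calls[i, j])]
                fields += [
                    matrix.allele_a[i] if a == "A" else matrix.allele_b[i] if a == "B" else "0",
                    matrix.allele_a[i] if b == "A" else matrix.allele_b[i] if b == "B" else "0",
                ]
            fh.write(" ".join(map(str, fields)) + "\n")
    return ped_path, map_path


def read_ped_map(
    prefix: str | Path,
    allele_a: list[str] | None = None,
    allele_b: list[str] | None = None,
) -> GenotypeMatrix:
    """Read PLINK text PED/MAP back into a GenotypeMatrix.

    The text dialect stores nucleotide alleles but not which is "reference",
    so by default allele A is the more frequent allele per marker (ties and
    monomorphic markers resolved alphabetically), the usual major/minor
    convention. Pass ``allele_a``/``allele_b`` to pin the polarity, e.g. for
    an exact fixture round-trip.
    """
    prefix = Path(prefix)
    chroms, mids, positions = [], [], []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            c, mid, _, p = line.split()
            chroms.append(c)
            mids.append(mid)
            positions.append(int(p))
    n = len(positions)
    samples: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            f = line.split()
            samples.append(f[1])
            alleles = f[6:]
            rows.append([(alleles[2 * i], alleles[2 * i + 1]) for i in range(n)])
    if allele_a is None or allele_b is None:
        allele_a = [""] * n
        allele_b = [""] * n
        for i in range(n):
            counts: dict[str, int] = {}
            for row in rows:
                for a in row[i]:
                    if a != "0":
                        counts[a] = counts.get(a, 0) + 1
            ranked = sorted(counts, key=lambda a: (-counts[a], a))
            allele_a[i] = ranked[0] if ranked else "A"
            allele_b[i] = ranked[1] if len(ranked) > 1 else ("B" if not ranked else ranked[0])
    calls = np.full((n, len(samples)), MISSING, dtype=np.int8)
    for j, row in enumerate(rows):
        for i, (a, b) in enumerate(row):
            if a == "0" or b == "0":
                continue
            code = (a == allele_b[i]) + (b == allele_b[i])
            calls[i, j] = code
    return GenotypeMatrix(
        np.array(chroms, dtype=object),
        np.array(positions),
        np.array(allele_a, dtype=object),
        np.array(allele_b, dtype=object),
        np.array(mids, dtype=object),
        samples,
        calls,
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tphenotype\trelation\tobligate_carrier\n")
        for r in sheet:
            fh.write(f"{r.sample}\t{r.phenotype}\t{r.relation}\t{int(r.obligate_carrier)}\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(
                SampleInfo(
                    d["sample"], d["phenotype"], d["relation"], bool(int(d["obligate_carrier"]))
                )
            )
    return SampleSheet(rows)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "causal_variant_id": truth.causal_variant_id,
        "planted_roh_intervals_per_case": {
            k: [list(iv) for iv in v] for k, v in truth.planted_roh_intervals_per_case.items()
        },
        "sample_roles": truth.sample_roles,
        "decoy_ids": truth.decoy_ids,
        "warnings": truth.warnings,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    return SimTruth(
        causal_variant_id=d["causal_variant_id"],
        planted_roh_intervals_per_case={
            k: [tuple(iv) for iv in v] for k, v in d["planted_roh_intervals_per_case"].items()
        },
        sample_roles=d["sample_roles"],
        decoy_ids=d["decoy_ids"],
        warnings=d["warnings"],
    )


def write_roh_tsv(segments: list[ROHSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart_bp\tend_bp\tn_snps\tkb\n")
        for s in segments:
            fh.write(
                f"{s.sample}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t{s.n_snps}\t{s.length_kb:.1f}\n"
            )


def write_regions(regions: list[SharedRegion], bed_path: str | Path, tsv_path: str | Path) -> None:
    """Shared regions as BED (0-based half-open) and TSV (1-based inclusive)."""
    with open(bed_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\tshared_roh\t{r.n_cases_supporting}\n")
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tstart_bp\tend_bp\tn_cases_supporting\tkb\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.n_cases_supporting}\t{r.length_kb:.1f}\n"
            )


def write_funnel(funnel: FilterFunnel, tsv_path: str | Path, json_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("Variant filtering steps\tNumber of variants\n")
        for label, n in funnel.stages:
            fh.write(f"{label}\t{n}\n")
    Path(json_path).write_text(
        json.dumps(
            {
                "stages": [{"label": l, "count": n} for l, n in funnel.stages],
                "surviving_ids": [sorted(ids) for ids in funnel.surviving_ids],
            },
            indent=1,
        )
    )


def write_fixture(bundle: SimBundle, out_dir: str | Path) -> dict:
    """Write a complete simulated study to ``out_dir``; returns the manifest.

    Emits reference FASTA, transcript GFF3, cohort and panel VCFs, PED/MAP
    array genotypes, the sample sheet TSV, truth BED/JSON and a manifest
    JSON listing every file with its record count. Reading the files back
    reproduces the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = {c: len(s) for c, s in bundle.reference.contigs.items()}

    write_fasta(bundle.reference.contigs, out / "reference.fa")
    write_gff3(bundle.reference.transcripts, out / "genes.gff3")
    cohort_samples = [s for s in bundle.cohort.samples if bundle.cohort.roles[s] != "panel"]
    panel_samples = bundle.cohort.sample_ids("panel")
    n_vcf = write_vcf(bundle.cohort, out / "cohort.vcf", lengths, cohort_samples)
    write_vcf(bundle.cohort, out / "panel.vcf", lengths, panel_samples)
    phenos = {s: 2 for s in bundle.config.case_ids}
    write_ped_map(bundle.array, out / "array", phenos)
    write_sample_sheet(bundle.sheet, out / "samples.tsv")
    write_truth(bundle.truth, out / "truth.json")
    with open(out / "truth_roh.bed", "w") as fh:
        for case, ivs in bundle.truth.planted_roh_intervals_per_case.items():
            for chrom, s, e in ivs:
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{case}\n")

    manifest = {
        "files": {
            "reference.fa": {"records": len(bundle.reference.contigs)},
            "genes.gff3": {"records": len(bundle.reference.transcripts)},
            "cohort.vcf": {"records": n_vcf, "samples": len(cohort_samples)},
            "panel.vcf": {"records": n_vcf, "samples": len(panel_samples)},
            "array.ped": {"records": len(bundle.array.samples)},
            "array.map": {"records": bundle.array.n_markers},
            "samples.tsv": {"records": len(bundle.sheet.rows)},
            "truth.json": {"records": 1},
            "truth_roh.bed": {
                "records": sum(len(v) for v in bundle.truth.planted_roh_intervals_per_case.values())
            },
        },
        "seed": bundle.config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
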