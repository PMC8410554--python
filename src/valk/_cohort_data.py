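"""Embedded study-cohort fixture data (partly synthetic).

The cohort emulates 28 liquid-biopsy samples (26 plasma, 2 CSF) from 24
ALK-positive NSCLC patients progressing on an ALK inhibitor.  The twelve
ALK kinase-domain rows, the eight non-ALK resistance rows and the three
copy-number events reproduce individually reported variants (allele
fractions, drugs, treatment lines, filter tiers, orthogonal dPCR MAFs and
inputs).  The remaining rows marked ``synthetic filler`` below are NOT
reported variants: they are constructed so that the cohort's aggregate
statistics come out at the reported values (61 somatic variants in 24 of
28 samples; 48 SNVs, 10 indels, 3 CNVs; 14 mutated genes; mean 2.18
variants per sample; median MAF 0.39% with range 0.02-5.09%; ALK
mutations in 10 of 26 plasma samples; three patients fully negative).

Genomic coordinates throughout are synthetic placeholders on the correct
chromosome; variant identity is carried by (gene, protein_change).
"""

from __future__ import annotations

# (sample_id, patient_id, specimen). Patients P03, P05 gave two samples on
# consecutive treatment lines; P19 gave three.  CSF: S04 (brain
# progression, BRAF-mutant) and S25 (brain-only progression, no ctDNA
# detected).  Patients P01, P07, P21 are mutation-negative.
SAMPLES = (
    ("S01", "P01", "plasma"), ("S02", "P02", "plasma"),
    ("S03", "P03", "plasma"), ("S04", "P03", "CSF"),
    ("S05", "P04", "plasma"), ("S06", "P05", "plasma"),
    ("S07", "P05", "plasma"), ("S08", "P06", "plasma"),
    ("S09", "P07", "plasma"), ("S10", "P08", "plasma"),
    ("S11", "P09", "plasma"), ("S12", "P10", "plasma"),
    ("S13", "P11", "plasma"), ("S14", "P12", "plasma"),
    ("S15", "P13", "plasma"), ("S16", "P14", "plasma"),
    ("S17", "P15", "plasma"), ("S18", "P16", "plasma"),
    ("S19", "P17", "plasma"), ("S20", "P18", "plasma"),
    ("S21", "P19", "plasma"), ("S22", "P19", "plasma"),
    ("S23", "P19", "plasma"), ("S24", "P20", "plasma"),
    ("S25", "P21", "CSF"), ("S26", "P22", "plasma"),
    ("S27", "P23", "plasma"), ("S28", "P24", "plasma"),
)

# ALK kinase-domain rows: (sample, cdna, protein_change, drug, line,
# expected_tier, maf_ngs_percent, maf_dpcr_percent, dpcr_input_ng,
# mol_depth).  Rows reported by the raw table only, despite an AF at or
# above the rescue floor, carry mol_depth 250 (below the 300 molecular-
# depth floor) — the only recorded variable that separates them from
# same-AF rescued rows; all other rows sit at the cohort-typical 1670.
ALK_ROWS = (
    ("S02", "c.3599C>T", "p.A1200V", "crizotinib", 1, "RAW_ONLY", 0.02, 0.04, 42.07, 1670),
    ("S03", "c.3806G>C", "p.G1269A", "crizotinib", 1, "COMMERCIAL", 3.36, 2.82, 4.64, 1670),
    ("S06", "c.3806G>C", "p.G1269A", "crizotinib", 1, "COMMERCIAL", 0.88, 0.42, 7.20, 1670),
    ("S07", "c.3604G>A", "p.G1202R", "ceritinib", 2, "COMMERCIAL", 1.28, 2.12, 54.04, 1670),
    ("S08", "c.3586C>A", "p.L1196M", "crizotinib", 1, "RAW_ONLY", 0.02, 0.06, 27.10, 1670),
    ("S18", "c.3617C>A", "p.S1206Y", "alectinib", 2, "VALK_RESCUED", 0.06, 0.01, 26.50, 1670),
    ("S18", "c.3604G>A", "p.G1202R", "alectinib", 2, "VALK_RESCUED", 0.04, 0.04, 26.50, 1670),
    ("S23", "c.3586C>A", "p.L1196M", "lorlatinib", 3, "RAW_ONLY", 0.05, 0.05, 29.24, 250),
    ("S23", "c.3824G>A", "p.R1275Q", "lorlatinib", 3, "RAW_ONLY", 0.03, 0.04, 21.80, 250),
    ("S24", "c.3604G>A", "p.G1202R", "alectinib", 2, "VALK_RESCUED", 0.05, 0.32, 14.11, 1670),
    ("S26", "c.3604G>A", "p.G1202R", "alectinib", 4, "VALK_RESCUED", 0.03, 0.01, 48.05, 1670),
    ("S28", "c.3538G>C", "p.V1180L", "alectinib", 1, "RAW_ONLY", 0.37, 0.35, 16.67, 250),
)

# Individually reported non-ALK small variants:
# (sample, gene, chrom, pos, ref, alt, class, protein_change, maf_percent,
#  hotspot_id)
OTHER_SMALL_ROWS = (
    ("S10", "IDH2", "chr15", 90631934, "C", "T", "SNV", "p.R140Q", 0.55, "COSM41590"),
    ("S16", "PIK3CA", "chr3", 178936091, "G", "A", "SNV", "p.E545K", 0.82, "COSM763"),
    ("S20", "PIK3CA", "chr3", 178936092, "A", "C", "SNV", "p.E545A", 0.48, "COSM12458"),
    ("S04", "BRAF", "chr7", 140481402, "C", "A", "SNV", "p.G466V", 0.65, "COSM451"),
    ("S12", "MAP2K1", "chr15", 66727455, "T", "C", "SNV", "p.F129L", 0.44, "COSM1570285"),
    ("S27", "MAP2K1", "chr15", 66727455, "T", "C", "SNV", "p.F129L", 0.41, "COSM1570285"),
    ("S21", "EGFR", "chr7", 55242464, "TGGAATTAAGAGAAGC", "T", "INDEL",
     "p.E746_A750del", 0.90, "COSM6223"),
    # co-mutations of the CNV-bearing sample
    ("S14", "TP53", "chr17", 7579358, "G", "C", "SNV", "p.P92A", 1.45, ""),
    ("S14", "TP53", "chr17", 7578406, "C", "A", "SNV", "p.V157F", 5.09, ""),
)

# Gene-level copy-number events: (sample, gene, chrom, pos, fold_change)
CNV_ROWS = (
    ("S14", "MYC", "chr8", 128748315, 3.08),
    ("S14", "CCND1", "chr11", 69455873, 0.38),
    ("S14", "FGFR3", "chr4", 1795039, 0.42),
)

# Synthetic filler (see module docstring): (sample, gene, class,
# protein_change, maf_percent).  Coordinates assigned programmatically.
FILLER_ROWS = (
    ("S02", "TP53", "SNV", "p.R175H", 0.04),
    ("S02", "TP53", "SNV", "p.R248Q", 0.05),
    ("S03", "TP53", "SNV", "p.R273H", 0.06),
    ("S05", "TP53", "SNV", "p.G245S", 0.07),
    ("S06", "TP53", "SNV", "p.R282W", 0.08),
    ("S08", "TP53", "SNV", "p.Y220C", 0.09),
    ("S10", "TP53", "SNV", "p.R249S", 0.10),
    ("S11", "TP53", "SNV", "p.H179R", 0.12),
    ("S13", "TP53", "SNV", "p.C176F", 0.14),
    ("S15", "TP53", "SNV", "p.M237I", 0.15),
    ("S17", "TP53", "SNV", "p.E285K", 0.17),
    ("S19", "TP53", "SNV", "p.R158L", 0.20),
    ("S21", "TP53", "SNV", "p.S241F", 0.22),
    ("S23", "TP53", "SNV", "p.G266E", 0.25),
    ("S04", "TP53", "SNV", "p.V272M", 0.27),
    ("S05", "TP53", "INDEL", "p.K132fs", 0.30),
    ("S12", "TP53", "INDEL", "p.P152fs", 0.32),
    ("S16", "TP53", "INDEL", "p.R209fs", 0.34),
    ("S24", "TP53", "INDEL", "p.T256fs", 0.35),
    ("S06", "SMAD4", "SNV", "p.R361H", 0.38),
    ("S13", "SMAD4", "SNV", "p.D351N", 0.40),
    ("S18", "SMAD4", "SNV", "p.A406T", 0.52),
    ("S07", "SMAD4", "INDEL", "p.E330fs", 0.60),
    ("S17", "SMAD4", "INDEL", "p.Q311fs", 0.70),
    ("S10", "FGFR2", "SNV", "p.S252W", 0.75),
    ("S15", "FGFR2", "SNV", "p.N550K", 0.95),
    ("S05", "FGFR2", "INDEL", "p.S267fs", 1.05),
    ("S11", "MET", "SNV", "p.D1228N", 1.15),
    ("S13", "MET", "SNV", "p.Y1230H", 1.30),
    ("S20", "MET", "SNV", "p.T1010I", 1.60),
    ("S12", "MET", "INDEL", "p.L982fs", 1.80),
    ("S16", "CCND3", "SNV", "p.I290T", 2.00),
    ("S17", "CCND3", "INDEL", "p.T283fs", 2.30),
    ("S19", "PIK3CA", "SNV", "p.H1047R", 2.60),
    ("S26", "PIK3CA", "SNV", "p.E542K", 3.00),
    ("S21", "EGFR", "SNV", "p.L858R", 3.60),
    ("S28", "EGFR", "SNV", "p.T790M", 4.20),
)

# chromosome and a synthetic base coordinate per panel gene
GENE_LOCATIONS = {
    "ALK": ("chr2", 29415640),
    "TP53": ("chr17", 7571720),
    "SMAD4": ("chr18", 48556583),
    "FGFR2": ("chr10", 123237844),
    "FGFR3": ("chr4", 1795039),
    "MET": ("chr7", 116312444),
    "CCND1": ("chr11", 69455873),
    "CCND3": ("chr6", 41902671),
    "PIK3CA": ("chr3", 178866311),
    "EGFR": ("chr7", 55086714),
    "BRAF": ("chr7", 140433812),
    "MYC": ("chr8", 128748315),
    "IDH2": ("chr15", 90627212),
    "MAP2K1": ("chr15", 66679211),
}

# cohort-typical run statistics
MEDIAN_READ_COV_PLASMA = 21261
MEDIAN_READ_COV_CSF = 9318
MEDIAN_MOL_COV = 1670.8
MAPPED_READS_PLASMA = 9_775_623
MAPPED_READS_CSF = 8_268_194
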