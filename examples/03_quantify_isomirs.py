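"""Assign cleaned reads to miRNAs and classify their isomiR type.

Each read is placed gaplessly on the mature sequences, allowing end
offsets up to 3 nt and up to 2 internal mismatches. End extensions are
compared with the hairpin: matching bases are 'templated', others
'non-templated'.
"""

import tempfile
from pathlib import Path

from plasmir import CohortConfig, count_samples, generate_cohort, preprocess_fastq
from plasmir.pipeline import _isomir_class_fractions
from plasmir.preprocess import _iter_fastq

cfg = CohortConfig(n_subjects=1, n_mirnas=40, library_depth_mean=8000,
                   mirna_fraction_mean=1.0, mirna_fraction_sd=0.0,
                   dropout_rate=0.0, seed=3)
cohort = generate_cohort(cfg)

with tempfile.TemporaryDirectory() as tmp:
    paths = cohort.write_fastq(tmp)
    sample, fastq = sorted(paths.items())[0]
    clean = Path(tmp) / "clean.fastq"
    preprocess_fastq(fastq, clean)
    reads = [seq for _, seq, _ in _iter_fastq(clean)]

cm, isomirs = count_samples({sample: reads}, cohort.reference)
print(f"assigned {int(cm.counts[sample].sum())} of {len(reads)} reads")
print(f"distinct isoforms observed: {len(isomirs)}")

print("\nread fraction per isomiR class:")
for label, frac in _isomir_class_fractions(isomirs, [sample]).items():
    print(f"  {label:18s} {frac:.3f}")
print("\nAbout a third of plasma miRNA reads match the canonical mature")
print("sequence; 3'-trimming is the most common modification, and templated")
print("3' extensions outnumber non-templated ones.")
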