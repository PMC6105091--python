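"""txweave: integrate transcript assemblies into a consolidated annotation.

The pipeline runs in three stages mirroring how the inputs arrive:

1. :mod:`txweave.prepare` — validate, strand-correct, deduplicate and sort
   transcript models from many assemblies into one GTF + cDNA FASTA.
2. :mod:`txweave.evidence` — collect trusted splice junctions, ORFs and
   protein-homology hits into a single store.
3. :mod:`txweave.pick` — cluster transcripts into loci, split chimeras,
   score transcripts against a configurable scoring file and select each
   locus's primary transcript plus valid splice variants.

:mod:`txweave.compare` measures any annotation against a reference with
class codes and six-level recall/precision/F1; :mod:`txweave.fixtures`
generates seeded synthetic datasets for testing.
"""

from .models import AnnotationSet, GenomicInterval, TranscriptModel

__version__ = "0.1.0"

__all__ = [
    "AnnotationSet",
    "GenomicInterval",
    "TranscriptModel",
    "__version__",
]
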