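"""Shared paths and the study-shaped configuration for the analysis scripts."""

from pathlib import Path

from cdikit.synthetic import CohortSpec

_ROOT = Path(__file__).resolve().parent.parent
#: small summary tables kept with the repository
RESULTS = _ROOT / "results" / "analysis"
#: large intermediates (matrices, attribution values) — regenerated on demand
DATA = _ROOT / "scratch" / "analysis_data"
RESULTS.mkdir(parents=True, exist_ok=True)
DATA.mkdir(parents=True, exist_ok=True)

SEED = 20260101 % (2**31 - 1)

#: the default generator spec IS the study-shaped cohort: 6 tissue datasets
#: (3 training) plus a 9-vs-9 strain mini-cohort, 93 planted DEGs (74 up /
#: 19 down), 16 strain-responsive drivers
COHORT = CohortSpec(seed=SEED)
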