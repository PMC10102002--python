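"""Shared down-scaled simulation scenario for fast unit tests.

Site means and the generic-hybrid mass scale with the library depth so the
abundance structure (trigger RPM far above the floor, the low-abundance
decoy below it) matches the full-size default scenario.
"""

import math

from tdmdscreen.synthetic import SimConfig

SMALL = SimConfig(
    n_mirnas=25,
    n_transcripts=60,
    reads_per_library=12_000,
    n_generic_sites=20,
    n_background_fragments=60,
    generic_log_mean=math.log(60.0),
    trigger_control_mean=8.0,
    low_abundance_control_mean=0.05,
    no_enrichment_control_mean=25.0,
)
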