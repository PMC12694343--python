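"""Bundled reference tables for worked examples and regression checks.

``field_survey_lag_summary`` is the published per-site, per-level
inter-peak-lag summary from a three-site riparian-woodland survey (sites
ordered by increasing distance from a highway; (2-2) peak mode, d4
filter, one analyzed day per site).  Only the measured columns are
bundled — mean lag [s], median lag [s], and peak count; the pairwise
comparison statistics (R, D) are derived quantities that
:func:`wavescape.peaks.compare_sites` recomputes from them.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["field_survey_lag_summary"]

_SURVEY_CSV = """\
site,level,mean_lag_s,median_lag_s,n_peaks
Site1,FULL,12.7,10,551
Site2,FULL,12.4,10,533
Site3,FULL,12.6,10,550
Site1,W1,11.9,10,623
Site2,W1,11.0,9,710
Site3,W1,11.0,9,722
Site1,W2,11.5,9,722
Site2,W2,10.0,8,842
Site3,W2,10.2,8,876
Site1,W3,10.4,8,875
Site2,W3,9.82,8,888
Site3,W3,10.0,8,916
Site1,W4,10.7,9,829
Site2,W4,10.6,9,833
Site3,W4,10.3,8,877
Site1,W5,12.1,10,641
Site2,W5,12.3,10,592
Site3,W5,11.8,9,713
Site1,W6,12.3,10,653
Site2,W6,12.7,11,611
Site3,W6,11.7,9,638
Site1,W7,12.8,10,570
Site2,W7,12.1,10,641
Site3,W7,12.7,10,622
Site1,W8,12.4,10,599
Site2,W8,12.7,10,601
Site3,W8,13.0,10,563
Site1,W9,12.4,10,582
Site2,W9,12.4,10,540
Site3,W9,12.7,10,559
Site1,W10,13.2,10,524
Site2,W10,12.4,10,553
Site3,W10,13.6,11,504
"""


def field_survey_lag_summary() -> pd.DataFrame:
    """Per-site, per-level lag summary of the bundled field survey."""
    return pd.read_csv(io.StringIO(_SURVEY_CSV))
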