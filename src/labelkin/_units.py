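"""Unit conventions shared across modules.

Chase time is expressed in weeks (the sampling grid of the experiment);
division times and dwell times in hours.  The conversion constant lives
here and nowhere else.
"""

HOURS_PER_WEEK = 168.0
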