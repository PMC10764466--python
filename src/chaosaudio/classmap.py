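"""Default sound-event class metadata.

The detector consumes (class, confidence) tables from an external
521-class everyday-sound classifier.  Each class carries an annotation
quality estimate, an exclusion flag for classes implausible in infant-worn
home recordings, a chaos group (``high`` / ``non_high``), and flags
marking the vehicle-like, cry-like and babble-like classes that the
pruning heuristics act on.

The shipped table covers the documented example classes per chaos level
plus a small extension list; the full class mapping used with a real
sound-event model is user-supplied configuration in the same CSV schema.
"""

from __future__ import annotations

import io

import pandas as pd

CRY_CLASS = "Baby cry, infant cry"
BABBLE_CLASS = "Babbling"
WHITE_NOISE_CLASS = "White noise"
VEHICLE_CLASSES = ("Car", "Traffic noise, roadway noise", "Vehicle", "Truck")

# class_name, quality_estimate, excluded, chaos_group, vehicle_like, cry_like, babble_like
_DEFAULT_CLASS_CSV = """\
class_name,quality_estimate,excluded,chaos_group,vehicle_like,cry_like,babble_like
Silence,0.90,0,non_high,0,0,0
White noise,0.80,0,non_high,0,0,0
Speech,0.90,0,non_high,0,0,0
"Child speech, kid speaking",0.80,0,non_high,0,0,0
Babbling,0.50,0,non_high,0,0,1
Singing,0.70,0,non_high,0,0,0
Piano,0.80,0,non_high,0,0,0
Classical music,0.80,0,non_high,0,0,0
Wind,0.60,0,non_high,0,0,0
Chime,0.70,0,non_high,0,0,0
Raindrop,0.50,0,non_high,0,0,0
Shuffling cards,0.60,0,non_high,0,0,0
Microwave oven,0.60,0,non_high,0,0,0
"Walk, footsteps",0.50,0,non_high,0,0,0
Toilet flush,0.80,0,non_high,0,0,0
Doorbell,0.70,0,non_high,0,0,0
Alarm clock,0.60,0,non_high,0,0,0
Hair dryer,0.60,0,non_high,0,0,0
Pop music,0.70,0,non_high,0,0,0
Acoustic guitar,0.80,0,non_high,0,0,0
"Violin, fiddle",0.80,0,non_high,0,0,0
Sink (filling or washing),0.60,0,non_high,0,0,0
Purr,0.70,0,non_high,0,0,0
Tearing,0.50,0,non_high,0,0,0
"Heart sounds, heartbeat",0.40,0,non_high,0,0,0
Children shouting,0.80,0,high,0,0,0
Screaming,0.90,0,high,0,0,0
Fire alarm,0.70,0,high,0,0,0
Applause,0.80,0,high,0,0,0
Drum roll,0.60,0,high,0,0,0
Electronic music,0.60,0,high,0,0,0
Chainsaw,0.70,0,high,0,0,0
Drill,0.60,0,high,0,0,0
Shatter,0.70,0,high,0,0,0
Bark,0.80,0,high,0,0,0
"Baby cry, infant cry",0.90,0,high,0,1,0
Car,0.80,0,high,1,0,0
"Traffic noise, roadway noise",0.70,0,high,1,0,0
Vehicle,0.60,0,high,1,0,0
Truck,0.50,0,high,1,0,0
Battle cry,0.30,0,high,0,0,0
Eruption,0.90,1,high,0,0,0
"Motorboat, speedboat",0.60,1,high,1,0,0
"""


def default_class_table() -> pd.DataFrame:
    """The shipped class-metadata table as a DataFrame."""
    df = pd.read_csv(io.StringIO(_DEFAULT_CLASS_CSV))
    for col in ("excluded", "vehicle_like", "cry_like", "babble_like"):
        df[col] = df[col].astype(bool)
    return df


def _retained(df: pd.DataFrame, quality_threshold: float = 0.33) -> pd.DataFrame:
    return df[(df["quality_estimate"] > quality_threshold) & (~df["excluded"])]


#: Retained class names by group — used by the synthetic prediction generator.
_table = _retained(default_class_table())
HIGH_CLASS_NAMES: tuple[str, ...] = tuple(
    _table[_table["chaos_group"] == "high"]["class_name"]
)
NON_HIGH_CLASS_NAMES: tuple[str, ...] = tuple(
    _table[_table["chaos_group"] == "non_high"]["class_name"]
)
del _table
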