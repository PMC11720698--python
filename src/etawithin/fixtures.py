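"""Embedded toy datasets used throughout the documentation and tests.

Five small worked datasets ship with the package, transcribed row by row
from their printed sources (working-memory scores for two age groups, a
longitudinal retest of one group, a 2x2 repeated-measures experiment,
face-attractiveness ratings with crossed participants and stimuli, and
bilingual text-reading times).  Each is stored in its printed wide
layout and reshaped to a long :class:`~etawithin.core_data.LongTable`
on load; a SHA-256 checksum over the canonical long form guards the
transcription.
"""

from __future__ import annotations

import hashlib
import io

import pandas as pd

from .core_data import LongTable, wide_to_long

__all__ = ["load_fixture", "list_fixtures", "fixture_checksum"]

# Working-memory scores, ten 65-year-olds vs ten 75-year-olds, two
# parallel tests on consecutive days.  Wide: one row per participant.
_WM_BETWEEN = """\
participant,group,day1,day2
p01,65yr,42,40
p02,65yr,23,23
p03,65yr,44,46
p04,65yr,20,20
p05,65yr,43,47
p06,65yr,37,37
p07,65yr,48,46
p08,65yr,53,53
p09,65yr,50,52
p10,65yr,33,33
p11,75yr,27,27
p12,75yr,35,37
p13,75yr,43,43
p14,75yr,51,49
p15,75yr,19,25
p16,75yr,52,50
p17,75yr,34,34
p18,75yr,24,26
p19,75yr,35,35
p20,75yr,23,21
"""

# The same ten 65-year-olds retested ten years later (longitudinal
# design), again twice per age.
_WM_LONGITUDINAL = """\
participant,a65_d1,a65_d2,a75_d1,a75_d2
p01,32,30,27,27
p02,38,42,35,37
p03,42,38,43,43
p04,57,55,51,49
p05,24,30,19,25
p06,57,49,52,50
p07,37,39,34,34
p08,33,33,24,26
p09,40,38,35,35
p10,22,20,23,21
"""

# 2x2 fully-within design (Day x StimulusType), two measurements per
# cell, crossed interaction with no main effects.
_TWOBYTWO = """\
participant,d1s1m1,d1s1m2,d1s2m1,d1s2m2,d2s1m1,d2s1m2,d2s2m1,d2s2m2
p01,3,3,5,5,5,3,1,4
p02,5,7,4,7,4,5,4,3
p03,4,3,4,4,5,6,2,3
p04,1,2,4,5,6,5,3,2
p05,6,4,8,8,8,9,7,9
p06,5,4,5,7,7,7,5,6
p07,6,6,7,7,7,4,8,5
p08,4,4,5,3,6,4,5,4
p09,5,3,6,3,5,6,6,7
p10,7,8,9,7,7,9,8,9
"""

# Attractiveness ratings (1-7) of ten 18-year-old faces by ten
# 18-year-old and ten 75-year-old raters: age is between participants,
# within stimuli.
_FACES = """\
participant,age,s01,s02,s03,s04,s05,s06,s07,s08,s09,s10
p01,yr18,4,3,2,4,2,5,3,5,1,6
p02,yr18,5,4,5,5,4,5,3,5,4,5
p03,yr18,5,3,2,5,2,2,5,5,2,3
p04,yr18,4,3,3,3,1,1,4,5,4,5
p05,yr18,7,2,4,6,2,3,3,4,2,4
p06,yr18,7,5,1,6,2,5,5,5,3,7
p07,yr18,7,3,2,4,1,4,3,5,5,5
p08,yr18,5,4,4,3,3,1,3,4,4,6
p09,yr18,4,4,5,4,2,5,4,5,4,5
p10,yr18,6,3,3,5,2,2,4,5,4,7
p11,yr75,6,2,5,3,1,4,1,3,3,5
p12,yr75,6,1,2,5,3,4,4,1,1,4
p13,yr75,5,2,1,2,3,2,3,1,1,5
p14,yr75,4,3,4,5,2,5,5,3,3,7
p15,yr75,4,1,4,3,1,3,1,1,1,5
p16,yr75,6,3,4,6,2,4,4,1,2,3
p17,yr75,7,3,5,6,4,4,2,2,2,4
p18,yr75,7,5,5,2,2,5,4,4,3,5
p19,yr75,5,3,5,4,2,3,2,1,3,5
p20,yr75,6,1,1,5,2,3,1,1,3,4
"""

# Seconds to read a 125-word text: 12 bilinguals read 20 texts, 5 per
# cell of Language (L1/L2) x Background knowledge (Yes/No).  Language and
# background are within participants, between texts.
_READING = """\
language,background,text,p01,p02,p03,p04,p05,p06,p07,p08,p09,p10,p11,p12
L1,Yes,t01,36,31,25,41,25,21,37,31,28,22,30,25
L1,Yes,t02,38,29,32,30,30,37,38,34,36,25,30,32
L1,Yes,t03,38,25,32,46,25,30,42,30,41,22,28,36
L1,Yes,t04,48,24,28,40,28,28,40,26,36,19,40,30
L1,Yes,t05,38,22,28,32,30,35,37,31,38,21,33,24
L1,No,t06,39,36,40,42,35,30,55,34,34,28,48,42
L1,No,t07,34,17,35,34,25,19,43,29,30,19,39,43
L1,No,t08,42,26,36,40,31,31,44,36,31,34,43,30
L1,No,t09,42,26,35,32,34,25,42,31,39,31,36,40
L1,No,t10,45,34,36,41,35,28,52,36,40,28,33,34
L2,Yes,t11,34,21,26,30,33,29,39,30,34,30,28,29
L2,Yes,t12,39,24,26,37,27,29,46,31,47,27,33,34
L2,Yes,t13,41,28,25,39,28,35,38,32,43,28,35,23
L2,Yes,t14,32,27,32,44,20,25,42,27,44,18,39,33
L2,Yes,t15,46,22,31,42,33,31,40,34,58,33,32,29
L2,No,t16,41,27,44,34,38,42,49,45,42,43,51,37
L2,No,t17,50,39,42,35,34,39,49,42,37,33,43,37
L2,No,t18,57,37,50,40,46,49,45,38,45,38,45,36
L2,No,t19,46,32,38,31,37,36,56,33,40,34,38,26
L2,No,t20,51,36,40,35,40,38,53,27,42,37,40,35
"""

# SHA-256 of the canonical long-format CSV of each fixture (see
# fixture_checksum); recomputed on every load to guard the transcription.
_CHECKSUMS = {
    "wm_between": "e51546e6410e818782224e69d5d69362018949a09c7bf0b40d6f2d8fb488449b",
    "wm_longitudinal": "0aa5639e0d0b85452a1fc2b06b27813e1ce96fac6f5b7be5ef4ca99c589d920a",
    "twobytwo": "8dd2ce280a236be2ea5a57466e8d6ab9b15f8a933a91682c6a070351376a89fe",
    "faces": "c4ccf8ed6b74547ecf3ef0fcf25c894deb443f2e6b0fd0d06fefe438f0347885",
    "reading": "e6713ff2eb1687012ee5f56c04dcd5b0166456727834cf8a0a242053d67f9f17",
}


def _build_wm_between() -> LongTable:
    wide = pd.read_csv(io.StringIO(_WM_BETWEEN), dtype=str)
    long = wide_to_long(
        wide, unit="participant", keep=["group"],
        mapping={"day1": {"day": "day1"}, "day2": {"day": "day2"}},
        response="score",
    )
    return LongTable(long, response="score", participant="participant",
                     factors=["group"], replicates=["day"])


def _build_wm_longitudinal() -> LongTable:
    wide = pd.read_csv(io.StringIO(_WM_LONGITUDINAL), dtype=str)
    mapping = {
        "a65_d1": {"age": "yr65", "day": "day1"},
        "a65_d2": {"age": "yr65", "day": "day2"},
        "a75_d1": {"age": "yr75", "day": "day1"},
        "a75_d2": {"age": "yr75", "day": "day2"},
    }
    long = wide_to_long(wide, unit="participant", mapping=mapping,
                        response="score")
    return LongTable(long, response="score", participant="participant",
                     factors=["age"], replicates=["day"])


def _build_twobytwo() -> LongTable:
    wide = pd.read_csv(io.StringIO(_TWOBYTWO), dtype=str)
    mapping = {}
    for d in ("1", "2"):
        for s in ("1", "2"):
            for m in ("1", "2"):
                mapping[f"d{d}s{s}m{m}"] = {
                    "day": f"day{d}", "stimulus_type": f"s{s}",
                    "measurement": f"m{m}",
                }
    long = wide_to_long(wide, unit="participant", mapping=mapping,
                        response="score")
    return LongTable(long, response="score", participant="participant",
                     factors=["day", "stimulus_type"],
                     replicates=["measurement"])


def _build_faces() -> LongTable:
    wide = pd.read_csv(io.StringIO(_FACES), dtype=str)
    mapping = {f"s{i:02d}": {"stimulus": f"s{i:02d}"} for i in range(1, 11)}
    long = wide_to_long(wide, unit="participant", keep=["age"],
                        mapping=mapping, response="rating")
    return LongTable(long, response="rating", participant="participant",
                     stimulus="stimulus", factors=["age"])


def _build_reading() -> LongTable:
    wide = pd.read_csv(io.StringIO(_READING), dtype=str)
    long = wide.melt(
        id_vars=["language", "background", "text"],
        var_name="participant", value_name="seconds",
    )
    return LongTable(long, response="seconds", participant="participant",
                     stimulus="text", factors=["language", "background"])


_BUILDERS = {
    "wm_between": _build_wm_between,
    "wm_longitudinal": _build_wm_longitudinal,
    "twobytwo": _build_twobytwo,
    "faces": _build_faces,
    "reading": _build_reading,
}


def list_fixtures() -> list[str]:
    """Names of the available embedded datasets."""
    return sorted(_BUILDERS)


def fixture_checksum(table: LongTable) -> str:
    """SHA-256 over the canonical long CSV (key-sorted rows, '%g' values)."""
    df = table.data.sort_values(table.key_columns).reset_index(drop=True)
    df[table.response] = df[table.response].map(lambda v: "%g" % v)
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def load_fixture(name: str, verify: bool = True) -> LongTable:
    """Return the long-format form of the named embedded dataset.

    Available names: ``wm_between`` (40 rows), ``wm_longitudinal`` (40),
    ``twobytwo`` (80), ``faces`` (200), ``reading`` (240).
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        ) from None
    table = builder()
    if verify:
        digest = fixture_checksum(table)
        if digest != _CHECKSUMS[name]:
            raise RuntimeError(
                f"fixture {name!r} failed its transcription checksum"
            )
    return table
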