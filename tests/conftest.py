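import textwrap

import pytest

from paleobracket import AgeInterval, FossilOccurrence, LineageRecord

#: Early-hominin record: occurrences at 7.5 (point), 6.0-5.7, 5.8-5.2 and
#: 4.4 Ma across 4 fossiliferous places; FAD dating envelope 6.5-7.5 Ma.
HOMININ_CSV = textwrap.dedent("""\
    taxon_id,lineage_id,locality_id,horizon_id,age_older_ma,age_younger_ma,region,axis_position,apomorphy,voucher
    Sahelanthropus,hominin,Toros-Menalla,TM266,7.5,6.5,Africa,,true,TM 266-01-060-1
    Orrorin,hominin,Tugen-Hills,LT1,6.0,5.7,Africa,,true,
    Ardipithecus,hominin,Middle-Awash,MA1,5.8,5.2,Africa,,true,
    Ardipithecus,hominin,Aramis,AR1,4.4,4.4,Africa,,true,
    """)


@pytest.fixture
def hominin_csv(tmp_path):
    path = tmp_path / "hominin.csv"
    path.write_text(HOMININ_CSV)
    return str(path)


@pytest.fixture
def hominin_record(hominin_csv):
    from paleobracket import group_records, read_occurrences

    # the hominin lineage is extant, but the worked analysis conditions on
    # the observed range (range basis), selected explicitly in tests
    return group_records(read_occurrences(hominin_csv), extant=True)["hominin"]


def make_record(ages, lineage_id="lin", extant=False, horizon_ids=None,
                axis_positions=None, apomorphy=True):
    """Build a LineageRecord from point ages (or (older, younger) tuples)."""
    occurrences = []
    for i, age in enumerate(ages):
        if isinstance(age, tuple):
            interval = AgeInterval(older=age[0], younger=age[1])
        else:
            interval = AgeInterval.point(age)
        occurrences.append(FossilOccurrence(
            taxon_id=f"t{i}",
            lineage_id=lineage_id,
            locality_id=f"loc{i}",
            horizon_id=horizon_ids[i] if horizon_ids else f"hz{i}",
            age=interval,
            region="testland",
            axis_position=axis_positions[i] if axis_positions else None,
            apomorphy_documented=apomorphy,
        ))
    return LineageRecord(lineage_id, extant, occurrences)
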