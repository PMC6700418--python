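import numpy as np
import pytest

import interflora as ifl


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded small synthetic community, shared across read-only tests."""
    return ifl.generate_dataset(ifl.preset("small", seed=11))


@pytest.fixture(scope="session")
def scored_small(small_dataset):
    return ifl.score_dataset(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240521)


MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:ko00900" org="ko" number="00900" title="minimal">
  <entry id="1" name="ko:K00001" type="ortholog"/>
</pathway>
"""

# two single-KO ortholog entries joined by one ECrel through pyruvate (C00022)
ECREL_KGML = """<?xml version="1.0"?>
<pathway name="path:ko00010" org="ko" number="00010" title="fixture">
  <entry id="1" name="ko:K00001" type="ortholog"/>
  <entry id="2" name="ko:K00002" type="ortholog"/>
  <entry id="3" name="cpd:C00022" type="compound"/>
  <relation entry1="1" entry2="2" type="ECrel">
    <subtype name="compound" value="3"/>
  </relation>
</pathway>
"""

MULTI_KO_KGML = """<?xml version="1.0"?>
<pathway name="path:ko00020" org="ko" number="00020" title="multi">
  <entry id="1" name="ko:K00001 ko:K00002" type="ortholog"/>
  <entry id="2" name="ko:K00003" type="ortholog"/>
  <entry id="3" name="cpd:C00033" type="compound"/>
  <relation entry1="1" entry2="2" type="ECrel">
    <subtype name="compound" value="3"/>
  </relation>
</pathway>
"""

# same K00001-K00002 edge as ECREL_KGML but through a different compound
ECREL_ALT_COMPOUND_KGML = """<?xml version="1.0"?>
<pathway name="path:ko00030" org="ko" number="00030" title="alt">
  <entry id="1" name="ko:K00001" type="ortholog"/>
  <entry id="2" name="ko:K00002" type="ortholog"/>
  <entry id="3" name="cpd:C00099" type="compound"/>
  <relation entry1="1" entry2="2" type="ECrel">
    <subtype name="compound" value="3"/>
  </relation>
</pathway>
"""

# producer K00010 on metabolic map 00040 maplinks to 02010 via C00022
PRODUCER_KGML = """<?xml version="1.0"?>
<pathway name="path:ko00040" org="ko" number="00040" title="producer">
  <entry id="1" name="ko:K00010" type="ortholog"/>
  <entry id="2" name="ko:K00011" type="ortholog"/>
  <entry id="3" name="cpd:C00050" type="compound"/>
  <entry id="4" name="cpd:C00022" type="compound"/>
  <entry id="5" name="path:ko02010" type="map"/>
  <relation entry1="1" entry2="2" type="ECrel">
    <subtype name="compound" value="3"/>
  </relation>
  <relation entry1="1" entry2="5" type="maplink">
    <subtype name="compound" value="4"/>
  </relation>
</pathway>
"""

# transporter K00099 on ABC-transporter map 02010 maplinks back via C00022
TRANSPORTER_KGML = """<?xml version="1.0"?>
<pathway name="path:ko02010" org="ko" number="02010" title="transporter">
  <entry id="1" name="ko:K00099" type="ortholog"/>
  <entry id="2" name="cpd:C00022" type="compound"/>
  <entry id="3" name="path:ko00040" type="map"/>
  <relation entry1="1" entry2="3" type="maplink">
    <subtype name="compound" value="2"/>
  </relation>
</pathway>
"""
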