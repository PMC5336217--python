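id: 3a
description: Stage 1, two refugia (Anatolia + Balkans) diverging in the Last Glacial
  Period, expansion Balkans->north-eastern Europe->western Europe (reconstructed
  from the Methods prose).
pools:
  pool1: N1
  pool2: N2
  pool3: N3
  pool4: N4
sampled_pools:
- pool1
- pool2
- pool3
- pool4
events:
- kind: merge
  time: t1
  source: pool4
  sink: pool3
- kind: merge
  time: t2
  source: pool3
  sink: pool2
- kind: merge
  time: t4
  source: pool2
  sink: pool1
- kind: size
  time: t4
  pool: pool1
  size: NA
priors:
  N1:
    dist: uniform
    low: 100
    high: 10000
  N2:
    dist: uniform
    low: 100
    high: 10000
  N3:
    dist: uniform
    low: 100
    high: 10000
  N4:
    dist: uniform
    low: 100
    high: 10000
  NA:
    dist: uniform
    low: 100
    high: 10000
  t1:
    dist: uniform
    low: 10
    high: 25
  t2:
    dist: uniform
    low: 20
    high: 60
  t4:
    dist: uniform
    low: 100
    high: 10000
constraints:
- t4 > t2
- t2 > t1
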