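id: 5a
description: 'Stage 1, two refugia (Anatolia + western Europe): independent dispersal
  from both into the Balkans with admixture, expansion from western to north-eastern
  Europe, and a final western-European decline (reconstructed from the Methods prose).'
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
- kind: size
  time: tm
  pool: pool4
  size: Nm
- kind: merge
  time: t1
  source: pool3
  sink: pool4
- kind: admix
  time: t2
  derived: pool2
  parent_a: pool1
  parent_b: pool4
  rate: ra
- kind: merge
  time: t4
  source: pool4
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
  Nm:
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
  tm:
    dist: uniform
    low: 1
    high: 10
  ra:
    dist: uniform
    low: 0.001
    high: 0.999
constraints:
- t4 > t2
- t2 > t1
- t1 > tm
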