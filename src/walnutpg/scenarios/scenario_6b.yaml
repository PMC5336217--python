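id: 6b
description: 'Stage 2, three refugia (Anatolia, Balkan ancestral pool NG1, western
  Europe): divergence of NG1 from Anatolia at t4 (size NA before), western Europe
  from NG1 at t3, Balkan admixture (rate ra from Anatolia) at t2, north-eastern
  Europe founded by admixture of western Europe (rate rb) and the Balkans at t1,
  expansion of pool 3 at td (from Nd), decline of pool 4 at tm (from Nm).'
pools:
  pool1: N1
  pool2: N2
  pool3: N3
  pool4: N4
  NG1: NG1
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
- kind: size
  time: td
  pool: pool3
  size: Nd
- kind: admix
  time: t1
  derived: pool3
  parent_a: pool4
  parent_b: pool2
  rate: rb
- kind: admix
  time: t2
  derived: pool2
  parent_a: pool1
  parent_b: NG1
  rate: ra
- kind: merge
  time: t3
  source: pool4
  sink: NG1
- kind: merge
  time: t4
  source: NG1
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
  Nd:
    dist: uniform
    low: 100
    high: 10000
  NG1:
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
  t3:
    dist: uniform
    low: 10
    high: 200
  t4:
    dist: uniform
    low: 100
    high: 10000
  td:
    dist: uniform
    low: 1
    high: 15
  tm:
    dist: uniform
    low: 1
    high: 10
  ra:
    dist: uniform
    low: 0.001
    high: 0.999
  rb:
    dist: uniform
    low: 0.001
    high: 0.999
constraints:
- t4 > t3
- t3 > t2
- t2 > t1
- t1 > td
- t3 > tm
- t1 > tm
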