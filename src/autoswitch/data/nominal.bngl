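# model: ampk_mtorc1_ulk1
begin parameters
  a1 0.001
  a2 0.001
  a3 0.001
  a4 1e-05
  a5 1e-05
  d1 0.01
  d2 0.1
  d3 0.1
  d3max 10.0
  d4 1.0
  d5 10.0
  p1 10.0
  p2 10.0
  p3 10.0
  p4 10.0
  p5 0.0001
  p6 1e-06
  p7 10.0
  p8 10.0
  p9 0.0
  u0 0.01
  u1 0.001
  u2 0.0001
  MTOR_total 20000.0
  RPTOR_total 20000.0
  ULK1_total 10000.0
  EIF4EBP1_total 10000.0
  AMBRA1_total 10000.0
  ampk_star 30000.0
  rapamycin_star 0.0
end parameters
begin molecule types
  rapa(mtor)
  AMPK(ulk1,T172~P,ST~0~P)
  MTOR(HEAT,FRB)
  RPTOR(RNC,ulk1,WD40,S792~0~P,S855_S859~0~P~PP)
  ULK1(straptor,stampk,S317~0~P,S758~0~P,S778~0~P)
  EIF4EBP1(RCR,S65_T70~0~P)
  AMBRA1(ST~0~P)
end molecule types
begin seed species
  rapa(mtor) rapamycin_star
  AMPK(ST~0,T172~P,ulk1) ampk_star
  MTOR(FRB,HEAT) MTOR_total
  RPTOR(RNC,S792~0,S855_S859~0,WD40,ulk1) RPTOR_total
  ULK1(S317~0,S758~0,S778~0,stampk,straptor) ULK1_total
  EIF4EBP1(RCR,S65_T70~0) EIF4EBP1_total
  AMBRA1(ST~0) AMBRA1_total
end seed species
begin reaction rules
  1: rapa(mtor) + MTOR(HEAT,FRB) <-> rapa(mtor!1).MTOR(HEAT,FRB!1) a1, d1
  2: RPTOR(WD40) + MTOR(HEAT,FRB) <-> RPTOR(WD40!1).MTOR(HEAT!1,FRB) a2, d2
  3A: RPTOR(RNC,ulk1,S792~0,S855_S859~0) + ULK1(straptor) -> RPTOR(RNC,ulk1!1,S792~0,S855_S859~0).ULK1(straptor!1) a3
  3B: RPTOR(ulk1!1).ULK1(straptor!1) -> RPTOR(ulk1) + ULK1(straptor) d3
  3C: RPTOR(ulk1!1,S792~P,S855_S859~PP).ULK1(straptor!1) -> RPTOR(ulk1,S792~P,S855_S859~PP) + ULK1(straptor) d3max
  4A: RPTOR(RNC,ulk1,S792~0,S855_S859~0) + EIF4EBP1(RCR,S65_T70~0) -> RPTOR(RNC!1,ulk1,S792~0,S855_S859~0).EIF4EBP1(RCR!1,S65_T70~0) a4
  4B: RPTOR(RNC!1).EIF4EBP1(RCR!1) -> RPTOR(RNC) + EIF4EBP1(RCR) d4
  5A: AMPK(ulk1,T172~P) + ULK1(stampk,S758~0) -> AMPK(ulk1!1,T172~P).ULK1(stampk!1,S758~0) a5
  5B: AMPK(ulk1!1).ULK1(stampk!1) -> AMPK(ulk1) + ULK1(stampk) d5
  6: MTOR(HEAT!1).RPTOR(WD40!1,ulk1!2).ULK1(straptor!2,stampk,S758~0) -> MTOR(HEAT!1).RPTOR(WD40!1,ulk1!2).ULK1(straptor!2,stampk,S758~P) p1
  7: MTOR(HEAT!1).RPTOR(WD40!1,RNC!2).EIF4EBP1(RCR!2,S65_T70~0) -> MTOR(HEAT!1).RPTOR(WD40!1,RNC!2).EIF4EBP1(RCR!2,S65_T70~P) p2
  8A: RPTOR(ulk1!1,S792~0).ULK1(straptor!1,S317~P,S778~P) -> RPTOR(ulk1!1,S792~P).ULK1(straptor!1,S317~P,S778~P) p3
  8B: RPTOR(ulk1!1,S855_S859~0).ULK1(straptor!1,S317~P,S778~P) -> RPTOR(ulk1!1,S855_S859~P).ULK1(straptor!1,S317~P,S778~P) 2*p4
  8C: RPTOR(ulk1!1,S855_S859~P).ULK1(straptor!1,S317~P,S778~P) -> RPTOR(ulk1!1,S855_S859~PP).ULK1(straptor!1,S317~P,S778~P) p4
  9: ULK1(straptor,S317~P,S778~P) + AMBRA1(ST~0) -> ULK1(straptor,S317~P,S778~P) + AMBRA1(ST~P) p5
  10: ULK1(straptor,S317~P,S778~P) + AMPK(ST~0) -> ULK1(straptor,S317~P,S778~P) + AMPK(ST~P) p6
  11A: AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,straptor,S317~0) -> AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,straptor,S317~P) p7
  11B: AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,S778~0) -> AMPK(ulk1!1,T172~P,ST~0).ULK1(stampk!1,S778~P) p8
  12: AMPK(T172~P) + RPTOR(S792~0) -> AMPK(T172~P) + RPTOR(S792~P) p9
  13: ULK1(S758~P) -> ULK1(S758~0) u0
  14: EIF4EBP1(S65_T70~P) -> EIF4EBP1(S65_T70~0) u0
  15A: RPTOR(S792~P) -> RPTOR(S792~0) u1
  15B: RPTOR(S855_S859~P) -> RPTOR(S855_S859~0) u0
  15C: RPTOR(S855_S859~PP) -> RPTOR(S855_S859~P) 2*u0
  16: AMBRA1(ST~P) -> AMBRA1(ST~0) u0
  17: AMPK(ST~P) -> AMPK(ST~0) u2
  18A: ULK1(straptor,S317~P) -> ULK1(straptor,S317~0) u0
  18B: ULK1(S778~P) -> ULK1(S778~0) u0
  19: RPTOR(S792~P) -> RPTOR(S792~0) u0
end reaction rules
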