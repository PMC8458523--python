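singer_id,station,date,theme_sequence,n_sequences
G3 13/04/11,G3,2011-04-13,Cb Cc,17
G3 13/04/13,G3,2013-04-13,Aa Ai,12
G3 17/04/11,G3,2011-04-17,Ea Cb Ba Aa,5
G3 16/04/13,G3,2013-04-16,Aa Ai An Ak Ac Ad,7
G2 19/04/11,G2,2011-04-19,Ba Aa,4
G2 20/04/13,G2,2013-04-20,Aa Ai Ac,7
G3 25/04/11,G3,2011-04-25,Ea Cb Ca Cc Ba,3
G2 27/04/13,G2,2013-04-27,Aa Ap Ai Aq Ac,3
G4 27/04/11,G4,2011-04-27,Cb Cc,4
G2 29/04/13,G2,2013-04-29,Aa Ac Ai Ak Ap,2
G3 28/04/11,G3,2011-04-28,Cb Cc Ca Ba Ea,2
G2 08/05/13,G2,2013-05-08,Ap Aa,10
G4 06/05/11,G4,2011-05-06,Ea Cb Cc Ca,8
G1 21/05/13,G1,2013-05-21,Aa Ai Ac,12
G2 09/05/11,G2,2011-05-09,Cb Cc,3
G1 29/05/13,G1,2013-05-29,Aa Ai Ac,10
G1 09/05/11,G1,2011-05-09,Ba Ac Aa,4
G1 30/05/13,G1,2013-05-30,Aa Ai Ac,2
G2 12/05/11,G2,2011-05-12,Cb Cc,9
W1305/06/13,W13,2013-06-05,Ga Ha Ec Ed Gb,7
G4 13/05/11,G4,2011-05-13,Ba Ac,13
G1 08/06/13,G1,2013-06-08,Cb Fa Ba Ca Aj Ak,2
G4 15/05/11,G4,2011-05-15,Ea Cb Cc Aa,3
G1 13/06/13,G1,2013-06-13,Aa Ac,16
G2 16/05/11,G2,2011-05-16,Cb Cc Ba Aa,4
G1 16/06/13,G1,2013-06-16,Aa Ai Ac Aq,22
G3 17/05/11,G3,2011-05-17,Aa Ea Cb Cc Ca Ba,5
W1316/06/13,W13,2013-06-16,Ai Ap,4
G1 18/05/11,G1,2011-05-18,Ba Aa Ac Bb Ab,3
G1 17/06/13,G1,2013-06-17,Ap Aa Ai,1
G1 21/05/11,G1,2011-05-21,Ba Aa Ac,21
W1305/10/13,W13,2013-10-05,Ed Gb Ga,4
G2 29/05/11,G2,2011-05-29,Cb Cc,7
G4 09/03/17,G4,2017-03-09,Df Ee,2
G1 15/06/11,G1,2011-06-15,Cc Cb Ba Aa Ea,15
G1 23/03/17,G1,2017-03-23,Bf Bd Bg Ee,1
G3 12/03/12,G3,2012-03-12,Aa Ba,8
G1 01/05/17,G1,2017-05-01,Bd Be Df Ee,21
G3 14/03/12,G3,2012-03-14,Ac Aa Af Da De Ba,1
G1 02/05/17,G1,2017-05-02,Bd Df Ee,5
G3 15/03/12,G3,2012-03-15,Ac Aa Ba,2
G1 04/05/17,G1,2017-05-04,Be Df Ee Bf,8
G4 17/03/12,G4,2012-03-17,Aa Ai Ba,1
G1 05/05/17,G1,2017-05-05,Bd Bg Df Ef Ee,1
G4 24/03/12,G4,2012-03-24,Aa Ac Ba,4
G1 07/05/17,G1,2017-05-07,Df Ee,10
G3 04/04/12,G3,2012-04-04,Aa Ac Ba,8
G1 08/05/17,G1,2017-05-08,Bg Df Ee,10
G4 07/04/12,G4,2012-04-07,Aa Ac Ba,2
G4 18/05/17,G4,2017-05-18,Df Bd Be Ee,11
G3 08/04/12,G3,2012-04-08,Ba Aa,17
G1 21/06/17,G1,2017-06-21,Bf Be Df,4
G4 10/04/12,G4,2012-04-10,Aa Ai Aj Ba,3
G1 23/06/17,G1,2017-06-23,Bd Be Df Ef,3
G3 12/04/12,G3,2012-04-12,Ba Aa Af Da,7
G1 24/06/17,G1,2017-06-24,Df Dg Bg,11
W6 05/03/13,W6,2013-03-05,Aa Ai Ac,4
G4 28/04/18,G4,2018-04-28,Bg Bd Be Df Ef Gd,4
W6 06/03/13,W6,2013-03-06,Ad Aa Ac,3
G4 03/05/18,G4,2018-05-03,Bd Df,12
W6 10/03/13,W6,2013-03-10,Aa Ai Ak Ac,6
G1 12/05/18,G1,2018-05-12,Gd Ge Gg Gh Ib,11
G3 11/03/13,G3,2013-03-11,Ai Ac,4
G4 17/05/18,G4,2018-05-17,Bh Bi,3
G3 15/03/13,G3,2013-03-15,Ac An Ak,5
G1 19/05/18,G1,2018-05-19,Gd Gf Gg Ge Bi Bb Bj,8
W9 29/03/13,W9,2013-03-29,Ap Aa,12
G1 23/05/18,G1,2018-05-23,Bi Bb Ib Bh Bc Gd Gh,2
G3 31/03/13,G3,2013-03-31,Aa Ai Ak Ac,13
G4 25/05/18,G4,2018-05-25,Gd Gf Gg Bh Bb Ba,2
G3 01/04/13,G3,2013-04-01,Ac Aa Ai,10
G1 31/05/18,G1,2018-05-31,Gd Ge,3
G3 03/04/13,G3,2013-04-03,Aa Ai Aj Ac Ad,4
G1 22/06/18,G1,2018-06-22,Gd Gg Bh Bi Bb,20
G1 05/04/13,G1,2013-04-05,Ac Aq Aa Am Ai An Ak,24
G1 01/07/18,G1,2018-07-01,Gd Gg Bh Bi Gh Bb Ge Gf Bc Bj Ib,4
G3 08/04/13,G3,2013-04-08,Aq Aa Am Ai Ac,1
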