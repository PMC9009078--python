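! DLPNO-MP2 RIJCOSX DefGrid3 NMR
%pointcharges "toy.pc"
%mp2
  DLPNO true
  MultiLevel true
  Fragment1PairLevel "NormalPNO"
  DefaultPairLevel "LoosePNO"
end
%eprnmr
  Nuclei = 0,1,2 { shift }
end
* xyz 0 1
  O (1)       1.178000       1.080000       0.946000  NewGTO "pcSseg-3" end
  H (1)       1.406612       0.217930       0.590793  NewGTO "pcSseg-3" end
  H (1)       2.009303       1.433081       1.272754  NewGTO "pcSseg-3" end
  O (2)       2.622000      -0.920000      -0.946000  NewGTO "def2-TZVP" end
  H (2)       2.393388      -1.782070      -0.590793  NewGTO "def2-TZVP" end
  H (2)       1.790697      -0.566919      -1.272754  NewGTO "def2-TZVP" end
  O (2)       2.622000       3.080000      -0.946000  NewGTO "def2-TZVP" end
  H (2)       2.393388       2.217930      -0.590793  NewGTO "def2-TZVP" end
  H (2)       1.790697       3.433081      -1.272754  NewGTO "def2-TZVP" end
  O (2)       2.622000       3.080000       3.354000  NewGTO "def2-TZVP" end
  H (2)       2.393388       2.217930       3.709207  NewGTO "def2-TZVP" end
  H (2)       1.790697       3.433081       3.027246  NewGTO "def2-TZVP" end
  O (2)       2.622000      -0.920000       3.354000  NewGTO "def2-TZVP" end
  H (2)       2.393388      -1.782070       3.709207  NewGTO "def2-TZVP" end
  H (2)       1.790697      -0.566919       3.027246  NewGTO "def2-TZVP" end
  O (2)       1.178000      -2.920000       0.946000  NewGTO "def2-TZVP" end
  H (2)       1.406612      -3.782070       0.590793  NewGTO "def2-TZVP" end
  H (2)       2.009303      -2.566919       1.272754  NewGTO "def2-TZVP" end
  O (2)       1.178000       5.080000       0.946000  NewGTO "def2-TZVP" end
  H (2)       1.406612       4.217930       0.590793  NewGTO "def2-TZVP" end
  H (2)       2.009303       5.433081       1.272754  NewGTO "def2-TZVP" end
*
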