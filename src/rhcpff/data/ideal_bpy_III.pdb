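HETATM    1  RH  RHC     1       0.000   0.000   0.000  1.00  0.00          Rh
HETATM    2  C1  RHC     1       0.000   1.227   1.820  1.00  0.00           C
HETATM    3  C2  RHC     1      -1.167   0.379   1.820  1.00  0.00           C
HETATM    4  C3  RHC     1      -0.721  -0.993   1.820  1.00  0.00           C
HETATM    5  C4  RHC     1       0.721  -0.993   1.820  1.00  0.00           C
HETATM    6  C5  RHC     1       1.167   0.379   1.820  1.00  0.00           C
HETATM    7  C6  RHC     1       0.000   2.737   1.820  1.00  0.00           C
HETATM    8  C7  RHC     1      -2.603   0.846   1.820  1.00  0.00           C
HETATM    9  C8  RHC     1      -1.609  -2.214   1.820  1.00  0.00           C
HETATM   10  C9  RHC     1       1.609  -2.214   1.820  1.00  0.00           C
HETATM   11  C10 RHC     1       2.603   0.846   1.820  1.00  0.00           C
HETATM   12  H1  RHC     1       0.000   3.101   2.850  1.00  0.00           H
HETATM   13  H2  RHC     1      -0.892   3.101   1.305  1.00  0.00           H
HETATM   14  H3  RHC     1       0.892   3.101   1.305  1.00  0.00           H
HETATM   15  H4  RHC     1      -2.949   0.958   2.850  1.00  0.00           H
HETATM   16  H5  RHC     1      -3.225   0.110   1.305  1.00  0.00           H
HETATM   17  H6  RHC     1      -2.674   1.806   1.305  1.00  0.00           H
HETATM   18  H7  RHC     1      -1.823  -2.509   2.850  1.00  0.00           H
HETATM   19  H8  RHC     1      -1.101  -3.033   1.305  1.00  0.00           H
HETATM   20  H9  RHC     1      -2.544  -1.985   1.305  1.00  0.00           H
HETATM   21  H10 RHC     1       1.823  -2.509   2.850  1.00  0.00           H
HETATM   22  H11 RHC     1       2.544  -1.985   1.305  1.00  0.00           H
HETATM   23  H12 RHC     1       1.101  -3.033   1.305  1.00  0.00           H
HETATM   24  H13 RHC     1       2.949   0.958   2.850  1.00  0.00           H
HETATM   25  H14 RHC     1       2.674   1.806   1.305  1.00  0.00           H
HETATM   26  H15 RHC     1       3.225   0.110   1.305  1.00  0.00           H
HETATM   27  N1  RHC     1      -0.930   1.307  -1.365  1.00  0.00           N
HETATM   28  C11 RHC     1      -1.613   0.708  -2.368  1.00  0.00           C
HETATM   29  C12 RHC     1      -2.269   1.486  -3.330  1.00  0.00           C
HETATM   30  C13 RHC     1      -2.217   2.873  -3.255  1.00  0.00           C
HETATM   31  C14 RHC     1      -1.515   3.488  -2.224  1.00  0.00           C
HETATM   32  C15 RHC     1      -0.865   2.716  -1.269  1.00  0.00           C
HETATM   33  H16 RHC     1      -2.725   3.480  -4.000  1.00  0.00           H
HETATM   34  H17 RHC     1      -1.474   4.572  -2.164  1.00  0.00           H
HETATM   35  H18 RHC     1      -0.316   3.198  -0.464  1.00  0.00           H
HETATM   36  H19 RHC     1      -2.818   1.007  -4.136  1.00  0.00           H
HETATM   37  N2  RHC     1      -0.930  -1.307  -1.365  1.00  0.00           N
HETATM   38  C16 RHC     1      -1.613  -0.708  -2.368  1.00  0.00           C
HETATM   39  C17 RHC     1      -2.269  -1.486  -3.330  1.00  0.00           C
HETATM   40  C18 RHC     1      -2.217  -2.873  -3.255  1.00  0.00           C
HETATM   41  C19 RHC     1      -1.515  -3.488  -2.224  1.00  0.00           C
HETATM   42  C20 RHC     1      -0.865  -2.716  -1.269  1.00  0.00           C
HETATM   43  H20 RHC     1      -2.725  -3.480  -4.000  1.00  0.00           H
HETATM   44  H21 RHC     1      -1.474  -4.572  -2.164  1.00  0.00           H
HETATM   45  H22 RHC     1      -0.316  -3.198  -0.464  1.00  0.00           H
HETATM   46  H23 RHC     1      -2.818  -1.007  -4.136  1.00  0.00           H
HETATM   47  CL  RHC     1       1.924   0.000  -1.450  1.00  0.00          Cl
CONECT    1    2    3    4    5
CONECT    1    6   27   37   47
CONECT    2    1    3    6    7
CONECT    3    1    2    4    8
CONECT    4    1    3    5    9
CONECT    5    1    4    6   10
CONECT    6    1    2    5   11
CONECT    7    2   12   13   14
CONECT    8    3   15   16   17
CONECT    9    4   18   19   20
CONECT   10    5   21   22   23
CONECT   11    6   24   25   26
CONECT   12    7
CONECT   13    7
CONECT   14    7
CONECT   15    8
CONECT   16    8
CONECT   17    8
CONECT   18    9
CONECT   19    9
CONECT   20    9
CONECT   21   10
CONECT   22   10
CONECT   23   10
CONECT   24   11
CONECT   25   11
CONECT   26   11
CONECT   27    1   28   32
CONECT   28   27   29   38
CONECT   29   28   30   36
CONECT   30   29   31   33
CONECT   31   30   32   34
CONECT   32   27   31   35
CONECT   33   30
CONECT   34   31
CONECT   35   32
CONECT   36   29
CONECT   37    1   38   42
CONECT   38   28   37   39
CONECT   39   38   40   46
CONECT   40   39   41   43
CONECT   41   40   42   44
CONECT   42   37   41   45
CONECT   43   40
CONECT   44   41
CONECT   45   42
CONECT   46   39
CONECT   47    1
END
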