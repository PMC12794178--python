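HETATM    1  RH  RHC     1       0.000   0.000   0.000  1.00  0.00          Rh
HETATM    2  C1  RHC     1       0.000   1.216   1.894  1.00  0.00           C
HETATM    3  C2  RHC     1      -1.157   0.376   1.894  1.00  0.00           C
HETATM    4  C3  RHC     1      -0.715  -0.984   1.894  1.00  0.00           C
HETATM    5  C4  RHC     1       0.715  -0.984   1.894  1.00  0.00           C
HETATM    6  C5  RHC     1       1.157   0.376   1.894  1.00  0.00           C
HETATM    7  C6  RHC     1       0.000   2.726   1.894  1.00  0.00           C
HETATM    8  C7  RHC     1      -2.593   0.843   1.894  1.00  0.00           C
HETATM    9  C8  RHC     1      -1.603  -2.206   1.894  1.00  0.00           C
HETATM   10  C9  RHC     1       1.603  -2.206   1.894  1.00  0.00           C
HETATM   11  C10 RHC     1       2.593   0.843   1.894  1.00  0.00           C
HETATM   12  H1  RHC     1       0.000   3.090   2.924  1.00  0.00           H
HETATM   13  H2  RHC     1      -0.892   3.090   1.379  1.00  0.00           H
HETATM   14  H3  RHC     1       0.892   3.090   1.379  1.00  0.00           H
HETATM   15  H4  RHC     1      -2.939   0.955   2.924  1.00  0.00           H
HETATM   16  H5  RHC     1      -3.215   0.107   1.379  1.00  0.00           H
HETATM   17  H6  RHC     1      -2.664   1.803   1.379  1.00  0.00           H
HETATM   18  H7  RHC     1      -1.817  -2.500   2.924  1.00  0.00           H
HETATM   19  H8  RHC     1      -1.095  -3.024   1.379  1.00  0.00           H
HETATM   20  H9  RHC     1      -2.538  -1.976   1.379  1.00  0.00           H
HETATM   21  H10 RHC     1       1.817  -2.500   2.924  1.00  0.00           H
HETATM   22  H11 RHC     1       2.538  -1.976   1.379  1.00  0.00           H
HETATM   23  H12 RHC     1       1.095  -3.024   1.379  1.00  0.00           H
HETATM   24  H13 RHC     1       2.939   0.955   2.924  1.00  0.00           H
HETATM   25  H14 RHC     1       2.664   1.803   1.379  1.00  0.00           H
HETATM   26  H15 RHC     1       3.215   0.107   1.379  1.00  0.00           H
HETATM   27  N1  RHC     1      -0.204   1.265  -1.555  1.00  0.00           N
HETATM   28  C11 RHC     1      -0.370   0.716  -2.816  1.00  0.00           C
HETATM   29  C12 RHC     1      -0.516   1.552  -3.929  1.00  0.00           C
HETATM   30  C13 RHC     1      -0.495   2.933  -3.770  1.00  0.00           C
HETATM   31  C14 RHC     1      -0.329   3.484  -2.504  1.00  0.00           C
HETATM   32  C15 RHC     1      -0.184   2.654  -1.399  1.00  0.00           C
HETATM   33  H16 RHC     1      -0.608   3.582  -4.634  1.00  0.00           H
HETATM   34  H17 RHC     1      -0.313   4.564  -2.381  1.00  0.00           H
HETATM   35  H18 RHC     1      -0.054   3.087  -0.410  1.00  0.00           H
HETATM   36  H19 RHC     1      -0.646   1.123  -4.920  1.00  0.00           H
HETATM   37  N2  RHC     1      -0.204  -1.265  -1.555  1.00  0.00           N
HETATM   38  C16 RHC     1      -0.370  -0.716  -2.816  1.00  0.00           C
HETATM   39  C17 RHC     1      -0.516  -1.552  -3.929  1.00  0.00           C
HETATM   40  C18 RHC     1      -0.495  -2.933  -3.770  1.00  0.00           C
HETATM   41  C19 RHC     1      -0.329  -3.484  -2.504  1.00  0.00           C
HETATM   42  C20 RHC     1      -0.184  -2.654  -1.399  1.00  0.00           C
HETATM   43  H20 RHC     1      -0.608  -3.582  -4.634  1.00  0.00           H
HETATM   44  H21 RHC     1      -0.313  -4.564  -2.381  1.00  0.00           H
HETATM   45  H22 RHC     1      -0.054  -3.087  -0.410  1.00  0.00           H
HETATM   46  H23 RHC     1      -0.646  -1.123  -4.920  1.00  0.00           H
CONECT    1    2    3    4    5
CONECT    1    6   27   37
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
END
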