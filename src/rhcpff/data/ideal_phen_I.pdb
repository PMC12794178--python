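HETATM    1  RH  RHC     1       0.000   0.000   0.000  1.00  0.00          Rh
HETATM    2  C1  RHC     1       0.000   1.218   1.888  1.00  0.00           C
HETATM    3  C2  RHC     1      -1.159   0.377   1.888  1.00  0.00           C
HETATM    4  C3  RHC     1      -0.716  -0.986   1.888  1.00  0.00           C
HETATM    5  C4  RHC     1       0.716  -0.986   1.888  1.00  0.00           C
HETATM    6  C5  RHC     1       1.159   0.377   1.888  1.00  0.00           C
HETATM    7  C6  RHC     1       0.000   2.728   1.888  1.00  0.00           C
HETATM    8  C7  RHC     1      -2.595   0.843   1.888  1.00  0.00           C
HETATM    9  C8  RHC     1      -1.604  -2.207   1.888  1.00  0.00           C
HETATM   10  C9  RHC     1       1.604  -2.207   1.888  1.00  0.00           C
HETATM   11  C10 RHC     1       2.595   0.843   1.888  1.00  0.00           C
HETATM   12  H1  RHC     1       0.000   3.092   2.918  1.00  0.00           H
HETATM   13  H2  RHC     1      -0.892   3.092   1.373  1.00  0.00           H
HETATM   14  H3  RHC     1       0.892   3.092   1.373  1.00  0.00           H
HETATM   15  H4  RHC     1      -2.941   0.956   2.918  1.00  0.00           H
HETATM   16  H5  RHC     1      -3.217   0.108   1.373  1.00  0.00           H
HETATM   17  H6  RHC     1      -2.665   1.804   1.373  1.00  0.00           H
HETATM   18  H7  RHC     1      -1.818  -2.502   2.918  1.00  0.00           H
HETATM   19  H8  RHC     1      -1.096  -3.026   1.373  1.00  0.00           H
HETATM   20  H9  RHC     1      -2.539  -1.978   1.373  1.00  0.00           H
HETATM   21  H10 RHC     1       1.818  -2.502   2.918  1.00  0.00           H
HETATM   22  H11 RHC     1       2.539  -1.978   1.373  1.00  0.00           H
HETATM   23  H12 RHC     1       1.096  -3.026   1.373  1.00  0.00           H
HETATM   24  H13 RHC     1       2.941   0.956   2.918  1.00  0.00           H
HETATM   25  H14 RHC     1       2.665   1.804   1.373  1.00  0.00           H
HETATM   26  H15 RHC     1       3.217   0.108   1.373  1.00  0.00           H
HETATM   27  N1  RHC     1      -0.187   1.267  -1.571  1.00  0.00           N
HETATM   28  C11 RHC     1      -0.336   0.707  -2.815  1.00  0.00           C
HETATM   29  C12 RHC     1      -0.470   1.528  -3.941  1.00  0.00           C
HETATM   30  C13 RHC     1      -0.453   2.910  -3.800  1.00  0.00           C
HETATM   31  C14 RHC     1      -0.303   3.478  -2.540  1.00  0.00           C
HETATM   32  C15 RHC     1      -0.169   2.663  -1.422  1.00  0.00           C
HETATM   33  H16 RHC     1      -0.557   3.549  -4.673  1.00  0.00           H
HETATM   34  H17 RHC     1      -0.290   4.559  -2.429  1.00  0.00           H
HETATM   35  H18 RHC     1      -0.052   3.109  -0.437  1.00  0.00           H
HETATM   36  N2  RHC     1      -0.187  -1.267  -1.571  1.00  0.00           N
HETATM   37  C16 RHC     1      -0.336  -0.707  -2.815  1.00  0.00           C
HETATM   38  C17 RHC     1      -0.470  -1.528  -3.941  1.00  0.00           C
HETATM   39  C18 RHC     1      -0.453  -2.910  -3.800  1.00  0.00           C
HETATM   40  C19 RHC     1      -0.303  -3.478  -2.540  1.00  0.00           C
HETATM   41  C20 RHC     1      -0.169  -2.663  -1.422  1.00  0.00           C
HETATM   42  H19 RHC     1      -0.557  -3.549  -4.673  1.00  0.00           H
HETATM   43  H20 RHC     1      -0.290  -4.559  -2.429  1.00  0.00           H
HETATM   44  H21 RHC     1      -0.052  -3.109  -0.437  1.00  0.00           H
HETATM   45  C21 RHC     1      -0.602   0.680  -5.048  1.00  0.00           C
HETATM   46  C22 RHC     1      -0.602  -0.680  -5.048  1.00  0.00           C
HETATM   47  H22 RHC     1      -0.712   1.244  -5.971  1.00  0.00           H
HETATM   48  H23 RHC     1      -0.712  -1.244  -5.971  1.00  0.00           H
CONECT    1    2    3    4    5
CONECT    1    6   27   36
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
CONECT   28   27   29   37
CONECT   29   28   30   45
CONECT   30   29   31   33
CONECT   31   30   32   34
CONECT   32   27   31   35
CONECT   33   30
CONECT   34   31
CONECT   35   32
CONECT   36    1   37   41
CONECT   37   28   36   38
CONECT   38   37   39   46
CONECT   39   38   40   42
CONECT   40   39   41   43
CONECT   41   36   40   44
CONECT   42   39
CONECT   43   40
CONECT   44   41
CONECT   45   29   46   47
CONECT   46   38   45   48
CONECT   47   45
CONECT   48   46
END
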