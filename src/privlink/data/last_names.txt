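ADAMS
AHMED
AITKEN
ALEXANDER
ALLAN
ALLEN
ANDERSON
ANDREWS
ARMSTRONG
ARNOLD
ATKINS
ATKINSON
BAILEY
BAKER
BALDWIN
BALL
BANKS
BARBER
BARKER
BARNES
BARRETT
BARRY
BARTLETT
BATES
BAXTER
BELL
BENNETT
BERRY
BISHOP
BLACK
BLAIR
BOOTH
BOWEN
BOYD
BRADLEY
BRADY
BREWER
BROOKS
BROWN
BRYANT
BURGESS
BURKE
BURNS
BURTON
BUTLER
BYRNE
CAMERON
CAMPBELL
CAREY
CARLSON
CARPENTER
CARR
CARROLL
CARTER
CASEY
CHAMBERS
CHAN
CHAPMAN
CHEN
CLARK
CLARKE
COLE
COLEMAN
COLLINS
CONNOLLY
COOK
COOPER
COSTELLO
COX
CRAWFORD
CROSS
CUNNINGHAM
CURTIS
DALTON
DALY
DANIELS
DAVIDSON
DAVIES
DAVIS
DAWSON
DAY
DEAN
DILLON
DIXON
DOHERTY
DONNELLY
DORAN
DOUGLAS
DOYLE
DUFFY
DUNCAN
DUNN
EDWARDS
ELLIOTT
ELLIS
EVANS
FARRELL
FERGUSON
FIELD
FINCH
FISHER
FITZGERALD
FITZPATRICK
FLEMING
FLETCHER
FLYNN
FORD
FOSTER
FOWLER
FOX
FRANCIS
FRASER
FREEMAN
FULLER
GALLAGHER
GARDNER
GARRETT
GIBSON
GILBERT
GILL
GLOVER
GOODWIN
GORDON
GRAHAM
GRANT
GRAY
GREEN
GREGORY
GRIFFIN
GRIFFITHS
HALL
HAMILTON
HAMMOND
HARDY
HARPER
HARRIS
HARRISON
HART
HARVEY
HAWKINS
HAYES
HENDERSON
HICKS
HIGGINS
HILL
HOBBS
HODGSON
HOGAN
HOLLAND
HOLMES
HOPKINS
HOWARD
HOWELL
HUGHES
HUNT
HUNTER
HUSSAIN
HUTCHINSON
INGRAM
JACKSON
JACOBS
JAMES
JARVIS
JENKINS
JENSEN
JOHNSON
JOHNSTON
JONES
JORDAN
KANE
KAUR
KEARNEY
KELLY
KENNEDY
KENNY
KHAN
KIM
KING
KIRK
KNIGHT
LAM
LAMBERT
LANE
LAWRENCE
LAWSON
LEE
LEWIS
LITTLE
LLOYD
LONG
LOPEZ
LOWE
LYNCH
LYONS
MACDONALD
MACKAY
MACKENZIE
MAHER
MANN
MARSH
MARSHALL
MARTIN
MASON
MATTHEWS
MAXWELL
MCBRIDE
MCCARTHY
MCCORMACK
MCDONALD
MCGRATH
MCGUIRE
MCINTYRE
MCKAY
MCKENZIE
MCLEAN
MCMAHON
MCMILLAN
MCNAMARA
MEYER
MILLER
MILLS
MITCHELL
MOLONEY
MOORE
MORAN
MORGAN
MORRIS
MORRISON
MULLINS
MURPHY
MURRAY
MYERS
NASH
NELSON
NEWMAN
NGUYEN
NICHOLLS
NOLAN
NORRIS
NORTON
OBRIEN
OCONNOR
ODONNELL
OLIVER
ONEILL
OSBORNE
OWEN
PALMER
PARKER
PARSONS
PATEL
PATERSON
PAYNE
PEARCE
PEARSON
PERRY
PETERS
PETERSEN
PHILLIPS
POOLE
POPE
PORTER
POTTER
POWELL
POWER
PRICE
QUINN
RAMSAY
READ
REED
REES
REID
REYNOLDS
RICHARDS
RICHARDSON
RILEY
ROBERTS
ROBERTSON
ROBINSON
ROGERS
ROSE
ROSS
ROWE
RUSSELL
RYAN
SANDERS
SAUNDERS
SCOTT
SHARP
SHAW
SHEPHERD
SIMPSON
SINCLAIR
SINGH
SLATER
SMITH
SPENCER
STEELE
STEPHENS
STEVENS
STEVENSON
STEWART
STONE
SULLIVAN
SUTHERLAND
SUTTON
TAYLOR
THOMAS
THOMPSON
THOMSON
TRAN
TUCKER
TURNER
WALKER
WALLACE
WALSH
WANG
WARD
WARREN
WATERS
WATKINS
WATSON
WATTS
WEBB
WEBSTER
WELLS
WEST
WHEELER
WHITE
WILKINSON
WILLIAMS
WILLIAMSON
WILLIS
WILSON
WONG
WOOD
WOODS
WRIGHT
YOUNG
ZHANG
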